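"""OTU abundance tables, from QIIME tables or best-hit alignment records.

16S OTU profiles arrive either as a pre-built QIIME classic table (parsed by
:mod:`taxalink.io_formats`) or as per-sample best-hit alignments of shotgun
reads against OTU consensus sequences, which this module tallies into a count
matrix.  The full OTU and sample universes are explicit inputs so that
zero-count rows and columns are representable — the prevalence filter needs
the complete denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import AlignmentHits, CountMatrix


def counts_from_alignments(
    hits: AlignmentHits,
    otu_ids: list[str],
    sample_ids: list[str],
) -> CountMatrix:
    """Tally best-hit alignment records into an OTU x sample count matrix.

    value(otu, sample) is the number of distinct read ids best-hit to that OTU
    in that sample; read ids are sample-scoped.  A read with conflicting
    references within one sample violates best-hit (k=1) semantics and is an
    error.  OTUs and samples with no hits appear as zero rows/columns.
    """
    otu_index = pd.Index(otu_ids)
    sample_index = pd.Index(sample_ids)
    if otu_index.has_duplicates or sample_index.has_duplicates:
        raise ValidationError("otu_ids and sample_ids must be unique")

    df = hits.drop_duplicates()
    key = df[["sample_id", "read_id"]]
    conflicts = key[key.duplicated()].drop_duplicates()
    if len(conflicts):
        pairs = list(conflicts.itertuples(index=False, name=None))
        raise ValidationError(
            f"(sample, read) pairs with conflicting references: {pairs[:5]}"
        )
    unknown_refs = set(df["reference_id"]) - set(otu_ids)
    if unknown_refs:
        raise ValidationError(f"unknown reference id(s): {sorted(unknown_refs)[:5]}")
    unknown_samples = set(df["sample_id"]) - set(sample_ids)
    if unknown_samples:
        raise ValidationError(f"unknown sample id(s): {sorted(unknown_samples)[:5]}")

    tally = (
        df.groupby(["reference_id", "sample_id"], sort=False).size().unstack(fill_value=0)
    )
    full = tally.reindex(index=otu_index, columns=sample_index, fill_value=0)
    return CountMatrix(full.astype(np.int64))


def merge_tables(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    """Row-wise concatenation of two count matrices over the same samples.

    Row id sets must be disjoint and sample id sets identical; b's columns are
    reordered to a's order and both row orders are preserved.
    """
    overlap = a.data.index.intersection(b.data.index)
    if len(overlap):
        raise ValidationError(f"overlapping row id(s): {list(overlap[:5])}")
    if set(a.sample_ids) != set(b.sample_ids):
        raise ValidationError("sample id sets differ between the two tables")
    merged = pd.concat([a.data, b.data.reindex(columns=a.data.columns)])
    return CountMatrix(merged)
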