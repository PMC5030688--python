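"""Technical-variability removal for shotgun gene counts.

Sequencing depth varies between samples; before abundances are comparable
across samples each sample is downsampled to a fixed number of mappable reads
and the counts are converted to relative abundance with the RPKM+TC scheme:
divide each count by its gene length, then by the per-sample total of the
length-normalized signal.  The constant "per kilobase per million" factors of
classic RPKM cancel under the total-count step, so they are omitted.
"""

from __future__ import annotations

import logging
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import AbundanceMatrix, CountMatrix, GeneLengthTable

logger = logging.getLogger(__name__)

OnShallow = Literal["error", "keep", "drop"]

#: Per-sample mappable-read target used on real data; synthetic runs scale down.
DEFAULT_TARGET_DEPTH = 15_000_000


def downsample_counts(
    counts: CountMatrix,
    target_depth: int,
    seed: int,
    on_shallow: OnShallow = "error",
) -> CountMatrix:
    """Subsample each sample's reads to a fixed depth, without replacement.

    Each column is treated as a finite pool of reads distributed over genes;
    ``target_depth`` reads are drawn uniformly without replacement (a
    multivariate hypergeometric draw), so the returned column total equals the
    target exactly.  Samples whose total is below the target are handled per
    ``on_shallow``: ``error`` aborts naming the sample, ``keep`` passes the
    column through unchanged with a warning, ``drop`` removes it.  The draw is
    fully reproducible given ``seed``.
    """
    if target_depth < 1:
        raise ValidationError("target_depth must be a positive integer")
    if on_shallow not in ("error", "keep", "drop"):
        raise ValidationError(f"unknown on_shallow policy: {on_shallow!r}")
    rng = np.random.default_rng(seed)
    values = counts.data.to_numpy()
    totals = values.sum(axis=0)

    shallow = [s for s, t in zip(counts.sample_ids, totals) if t < target_depth]
    if shallow and on_shallow == "error":
        raise ValidationError(
            f"sample(s) below target depth {target_depth}: {shallow[:5]}"
        )
    if shallow:
        logger.warning(
            "%d sample(s) below target depth %d (%s): %s",
            len(shallow), target_depth, on_shallow, shallow[:5],
        )

    out: dict[str, np.ndarray] = {}
    for j, sample in enumerate(counts.sample_ids):
        column = values[:, j]
        if totals[j] < target_depth:
            if on_shallow == "drop":
                continue
            out[sample] = column
        elif totals[j] == target_depth:
            out[sample] = column
        else:
            out[sample] = rng.multivariate_hypergeometric(
                column, target_depth, method="marginals"
            )
    df = pd.DataFrame(out, index=counts.data.index, dtype=np.int64)
    return CountMatrix(df)


class RpkmTcResult(NamedTuple):
    abundance: AbundanceMatrix
    zero_samples: list[str]


def normalize_rpkm_tc(counts: CountMatrix, lengths: GeneLengthTable) -> RpkmTcResult:
    """Convert gene counts to relative abundance by RPKM+TC.

    abundance(g, s) = (count(g, s) / length(g)) / sum_g' (count(g', s) / length(g')).

    Columns with no signal at all are returned as all zeros and listed in
    ``zero_samples``.  Every gene present in ``counts`` must have a length.
    """
    missing = counts.data.index.difference(lengths.index)
    if len(missing):
        raise ValidationError(
            f"gene(s) without a length entry: {list(missing[:5])}"
        )
    length_vec = lengths.reindex(counts.data.index).to_numpy(dtype=np.float64)
    rates = counts.data.to_numpy(dtype=np.float64) / length_vec[:, None]
    colsums = rates.sum(axis=0)
    zero_mask = colsums == 0
    zero_samples = [s for s, z in zip(counts.sample_ids, zero_mask) if z]
    if zero_samples:
        logger.warning("all-zero sample(s) left as zeros: %s", zero_samples[:5])
    safe = np.where(zero_mask, 1.0, colsums)
    abundance = rates / safe
    df = pd.DataFrame(abundance, index=counts.data.index, columns=counts.data.columns)
    return RpkmTcResult(AbundanceMatrix(df), zero_samples)
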