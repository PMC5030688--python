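"""The core linking method: correlate OTU and MGS abundance profiles.

Both abundance tables are normalized per sample to ratios, a small pseudocount
(1e-17) is added on the ratio scale to avoid log underflow, and values are
log10-transformed to control variation and damp extreme values.  Rows present
in too few samples (positive counts in no more than 10 samples by default) are
removed first, because sparse profiles produce spurious correlations.  Every
query row is then correlated (Pearson) against every candidate row of the
other table, and the best and second-best hits are reported against a cutoff
(0.65 by default, inclusive).

Pearson correlation is invariant to the log base (an affine rescaling); base
10 makes a zero count map exactly to -17, a convenient sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import CountMatrix

DEFAULT_PSEUDOCOUNT = 1e-17
DEFAULT_CUTOFF = 0.65
DEFAULT_MIN_PREVALENCE = 10


@dataclass(frozen=True)
class LinkResult:
    """Best and second-best hit for one query profile.

    ``best_r >= second_r`` whenever both are present; ``passes_cutoff`` is
    true iff the best correlation reaches the cutoff.  A query whose
    correlations are all undefined has no best hit and never passes.
    """

    query_id: str
    best_id: str | None
    best_r: float | None
    second_id: str | None
    second_r: float | None
    passes_cutoff: bool
    n_candidates: int


def normalize_profiles(
    m: CountMatrix | pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-sample ratio conversion followed by log10 with a pseudocount.

    value(e, s) = log10(m(e, s) / colsum(s) + pseudocount).  The pseudocount
    acts on the ratio scale, where 1e-17 sits far below any real relative
    abundance, so a zero count maps exactly to log10(pseudocount).  All-zero
    columns cannot be converted to ratios and must be dropped by the caller
    first.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    df = m.data if isinstance(m, CountMatrix) else m
    values = df.to_numpy(dtype=np.float64)
    if values.size and values.min() < 0:
        raise ValidationError("profiles must be non-negative")
    colsums = values.sum(axis=0)
    zero = colsums == 0
    if zero.any():
        raise ValidationError(
            f"all-zero sample column(s): {list(df.columns[zero][:5])}; drop them first"
        )
    out = np.log10(values / colsums + pseudocount)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def prevalence_filter(
    m: CountMatrix | pd.DataFrame,
    min_positive_exclusive: int = DEFAULT_MIN_PREVALENCE,
) -> tuple[CountMatrix | pd.DataFrame, list[str]]:
    """Drop rows positive in too few samples.

    A row is retained iff its number of samples with value > 0 is strictly
    greater than ``min_positive_exclusive`` ("positive counts in more than N
    samples").  Returns the filtered matrix and the dropped row ids.
    """
    df = m.data if isinstance(m, CountMatrix) else m
    positives = (df.to_numpy() > 0).sum(axis=1)
    keep = positives > min_positive_exclusive
    dropped = [str(r) for r, k in zip(df.index, keep) if not k]
    filtered = df.loc[keep]
    if isinstance(m, CountMatrix):
        return CountMatrix(filtered), dropped
    return filtered, dropped


def pearson_cross(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every row of ``a`` against every row of ``b``.

    Both matrices must share the same samples in the same order, with at
    least 3 of them.  Pairs where either row is constant have no defined
    correlation and are returned as NaN; they are excluded from hit ranking.
    """
    if list(a.columns) != list(b.columns):
        raise ValidationError("sample ids (and order) must match between tables")
    n = a.shape[1]
    if n < 3:
        raise ValidationError("pearson_cross requires at least 3 samples")
    av = a.to_numpy(dtype=np.float64)
    bv = b.to_numpy(dtype=np.float64)
    ac = av - av.mean(axis=1, keepdims=True)
    bc = bv - bv.mean(axis=1, keepdims=True)
    asd = np.sqrt((ac**2).sum(axis=1))
    bsd = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (ac @ bc.T) / np.outer(asd, bsd)
    corr[asd == 0, :] = np.nan
    corr[:, bsd == 0] = np.nan
    np.clip(corr, -1.0, 1.0, out=corr)
    return pd.DataFrame(corr, index=a.index, columns=b.index)


def best_hits(
    corr: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    direction: Literal["query_rows", "query_cols"] = "query_rows",
) -> list[LinkResult]:
    """Best and second-best candidate per query, against the cutoff.

    Candidates are ranked by decreasing correlation with ties broken by
    ascending candidate id, so the result is deterministic and invariant to
    candidate order.  Undefined (NaN) correlations never rank: a query whose
    correlations are all undefined yields a result with no best hit.
    """
    if corr.size == 0:
        raise ValidationError("empty correlation table")
    if direction == "query_cols":
        corr = corr.T
    elif direction != "query_rows":
        raise ValidationError(f"unknown direction: {direction!r}")

    candidate_ids = np.array([str(c) for c in corr.columns])
    order0 = np.argsort(candidate_ids, kind="stable")  # id tiebreak baseline
    results: list[LinkResult] = []
    values = corr.to_numpy(dtype=np.float64)
    for query_id, row in zip(corr.index, values):
        row = row[order0]
        ids = candidate_ids[order0]
        defined = ~np.isnan(row)
        n_cand = int(defined.sum())
        if n_cand == 0:
            results.append(
                LinkResult(str(query_id), None, None, None, None, False, 0)
            )
            continue
        row = row[defined]
        ids = ids[defined]
        # stable sort on -r keeps the ascending-id order within ties
        ranked = np.argsort(-row, kind="stable")
        best_i = ranked[0]
        best_id, best_r = str(ids[best_i]), float(row[best_i])
        second_id = second_r = None
        if n_cand > 1:
            second_i = ranked[1]
            second_id, second_r = str(ids[second_i]), float(row[second_i])
        results.append(
            LinkResult(
                str(query_id), best_id, best_r, second_id, second_r,
                best_r >= cutoff, n_cand,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Links table I/O (TSV, one row per query)
# ---------------------------------------------------------------------------

_LINK_COLUMNS = [
    "query_id", "best_id", "best_r", "second_id", "second_r",
    "passes_cutoff", "n_candidates",
]


def links_to_frame(links: list[LinkResult]) -> pd.DataFrame:
    rows = [
        (
            l.query_id, l.best_id,
            "" if l.best_r is None else f"{l.best_r:.10g}",
            l.second_id,
            "" if l.second_r is None else f"{l.second_r:.10g}",
            str(l.passes_cutoff).lower(), l.n_candidates,
        )
        for l in links
    ]
    return pd.DataFrame(rows, columns=_LINK_COLUMNS)


def write_links(links: list[LinkResult], path: str | Path) -> None:
    links_to_frame(links).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_links(path: str | Path) -> list[LinkResult]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if list(df.columns) != _LINK_COLUMNS:
        raise ValidationError(f"links table must have columns {_LINK_COLUMNS}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            LinkResult(
                row.query_id,
                row.best_id or None,
                float(row.best_r) if row.best_r else None,
                row.second_id or None,
                float(row.second_r) if row.second_r else None,
                row.passes_cutoff == "true",
                int(row.n_candidates),
            )
        )
    return out
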