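"""Per-MGS abundance profiles via co-abundance connectivity and tracer genes.

A metagenomic species (MGS) is a set of catalog genes whose abundances co-vary
across samples.  Its abundance signal is summarized by "tracer" genes: within
each MGS a gene co-abundance network is built (an edge between two member
genes when their Spearman correlation across samples reaches a threshold,
0.7 by default), genes are ordered by decreasing connectivity, and the mean
profile of the 50 most connected genes is the MGS abundance vector.  High
connectivity selects core genes and demotes accessory genes, whose
presence/absence patterns deviate from the organism's abundance.

Connectivity is computed on the relative-abundance matrix (post RPKM+TC,
pre log transform); rank correlation is invariant to the monotone log step,
so the network is unaffected by that choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .io_formats import MgsMembership

logger = logging.getLogger(__name__)

DEFAULT_RHO_THRESHOLD = 0.7
DEFAULT_N_TRACERS = 50


@dataclass(frozen=True)
class ConnectivityReport:
    """Connectivity of one gene within its MGS's co-abundance network.

    ``degree`` counts co-member genes whose Spearman correlation with this
    gene is defined and at or above the threshold.  A gene whose profile is
    constant across samples has no defined correlations; it is flagged and
    has degree 0.
    """

    gene_id: str
    degree: int
    constant: bool = False


@dataclass(frozen=True)
class MgsModel:
    """One MGS: its member genes, selected tracer genes and optional genus."""

    mgs_id: str
    member_genes: tuple[str, ...]
    tracer_genes: tuple[str, ...]
    genus: str | None = None

    def __post_init__(self) -> None:
        if not set(self.tracer_genes) <= set(self.member_genes):
            raise ValidationError(
                f"{self.mgs_id}: tracer genes must be a subset of member genes"
            )


def spearman_rho(x, y) -> float | None:
    """Spearman rank correlation: Pearson on average-ranked values.

    Returns None (undefined) when either vector is constant — a constant
    profile carries no ordering information, and treating the correlation as
    0 would let such genes form spurious network edges.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValidationError("spearman_rho requires 1-d vectors of length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return None
    return float(np.corrcoef(rx, ry)[0, 1])


def gene_connectivity(
    abundance: pd.DataFrame,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
) -> list[ConnectivityReport]:
    """Connectivity of each gene in an MGS-restricted abundance matrix.

    ``abundance`` holds only one MGS's member genes (rows) across samples.
    degree(g) = number of other member genes g' with a defined Spearman
    correlation rho(g, g') >= ``rho_threshold``.  The relation is symmetric by
    construction.  Constant-profile genes are flagged with degree 0.
    """
    genes = [str(g) for g in abundance.index]
    if len(genes) == 0:
        raise ValidationError("gene_connectivity requires at least one gene")
    values = abundance.to_numpy(dtype=np.float64)
    if len(genes) == 1:
        logger.warning("MGS with a single gene in the matrix: %s", genes[0])
        constant = bool(np.ptp(values[0]) == 0)
        return [ConnectivityReport(genes[0], 0, constant=constant)]

    ranks = rankdata(values, axis=1)
    constant = np.ptp(ranks, axis=1) == 0
    degrees = np.zeros(len(genes), dtype=np.int64)
    usable = ~constant
    if usable.sum() >= 2:
        sub = ranks[usable]
        corr = np.corrcoef(sub)
        np.fill_diagonal(corr, -np.inf)  # self never counts
        degrees[usable] = (corr >= rho_threshold).sum(axis=1)
    return [
        ConnectivityReport(g, int(d), constant=bool(c))
        for g, d, c in zip(genes, degrees, constant)
    ]


def select_tracers(
    connectivity: list[ConnectivityReport],
    k: int = DEFAULT_N_TRACERS,
) -> list[str]:
    """Select the k most connected genes, ties broken by ascending gene id.

    Constant-profile genes carry no co-abundance signal and are never
    selected; if fewer than k usable genes exist, all of them are returned.
    """
    if not connectivity:
        raise ValidationError("select_tracers requires a non-empty connectivity list")
    if k < 1:
        raise ValidationError("k must be a positive integer")
    usable = [c for c in connectivity if not c.constant]
    ordered = sorted(usable, key=lambda c: (-c.degree, c.gene_id))
    return [c.gene_id for c in ordered[:k]]


def build_mgs_models(
    abundance: pd.DataFrame,
    membership: MgsMembership,
    k: int = DEFAULT_N_TRACERS,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
) -> list[MgsModel]:
    """Build an MgsModel per MGS from the gene abundance matrix.

    Member genes absent from the matrix are ignored with a warning; an MGS
    with no usable (non-constant) gene in the matrix is skipped with a
    warning, since it cannot carry an abundance signal.
    """
    present = membership.index.intersection(abundance.index)
    absent = membership.index.difference(abundance.index)
    if len(absent):
        logger.warning(
            "%d member gene(s) absent from the abundance matrix", len(absent)
        )
    models: list[MgsModel] = []
    by_mgs = membership.loc[present].groupby(membership.loc[present]).groups
    for mgs_id in sorted(by_mgs):
        genes = [str(g) for g in by_mgs[mgs_id]]
        conn = gene_connectivity(abundance.loc[genes], rho_threshold)
        tracers = select_tracers(conn, k) if any(not c.constant for c in conn) else []
        if not tracers:
            logger.warning("MGS %s has no usable tracer gene; skipped", mgs_id)
            continue
        models.append(MgsModel(str(mgs_id), tuple(genes), tuple(tracers)))
    return models


def mgs_abundance(abundance: pd.DataFrame, models: list[MgsModel]) -> pd.DataFrame:
    """Mean tracer vector per MGS (MGS x samples).

    row(mgs, s) is the arithmetic mean over the MGS's tracer genes of
    abundance(g, s).  Rows are means of relative abundances, so columns of the
    result need not sum to 1.
    """
    rows = {}
    for model in models:
        if not model.tracer_genes:
            raise ValidationError(f"MGS {model.mgs_id} has an empty tracer list")
        missing = [g for g in model.tracer_genes if g not in abundance.index]
        if missing:
            raise ValidationError(
                f"MGS {model.mgs_id}: tracer gene(s) missing from matrix: {missing[:5]}"
            )
        rows[model.mgs_id] = abundance.loc[list(model.tracer_genes)].mean(axis=0)
    return pd.DataFrame(rows).T.reindex(columns=abundance.columns)
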