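"""Synthetic paired shotgun-gene / 16S-OTU communities with a known answer key.

The generator emulates the statistical structure the linking method relies
on: each organism has a latent log-normal abundance across samples, its
catalog genes produce shotgun counts proportional to abundance x gene length
x sequencing depth (Poisson noise), and its 16S OTUs — possibly several,
since 16S is a multicopy gene — track the same latent abundance scaled by
copy number in the amplicon table.  Two kinds of confounder can be injected:
organism pairs with correlated latent abundance (ecological co-association)
and near-identical relatives sharing a niche.  A configurable fraction of
each organism's genes is "accessory": present only in a random subset of
samples, so its profile deviates from the core genome — the hard case that
tracer selection is meant to demote.  The full OTU -> organism -> MGS truth
is returned for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import CountMatrix, GeneLengthTable, MgsMembership


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the simulated community.

    Defaults follow the scale of the real study where one exists (138
    samples; 1-3 16S copies treated as distinct OTUs) and otherwise describe
    a moderately diverse gut-like community whose organism abundances spread
    over a few orders of magnitude (log10-ish spread from
    ``log_abundance_sigma`` = 1.5 natural-log units).
    """

    n_organisms: int = 40
    n_samples: int = 138
    genes_per_organism: tuple[int, int] = (80, 150)
    gene_length_range: tuple[int, int] = (300, 3000)  # nucleotides
    otus_per_organism: tuple[int, int] = (1, 3)
    log_abundance_sigma: float = 1.5  # sd of log latent abundance
    shotgun_depth: int = 200_000  # mappable reads per sample
    amplicon_depth: int = 20_000  # 16S reads per sample
    n_confounded_pairs: int = 0  # co-associated organism pairs
    rho_conf: float = 0.99  # latent correlation of confounded pairs
    n_near_relatives: int = 0  # near-identical relative pairs
    rho_rel: float = 0.95
    accessory_fraction: float = 0.10  # fraction of genes with patchy presence
    accessory_prevalence: float = 0.60  # per-sample presence probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organisms < 1 or self.n_samples < 1:
            raise ValidationError("n_organisms and n_samples must be >= 1")
        for name in ("genes_per_organism", "gene_length_range", "otus_per_organism"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValidationError(f"{name} must satisfy 1 <= lo <= hi")
        if self.log_abundance_sigma < 0:
            raise ValidationError("log_abundance_sigma must be >= 0")
        if self.shotgun_depth < 1 or self.amplicon_depth < 1:
            raise ValidationError("depths must be positive")
        for name in ("rho_conf", "rho_rel"):
            if not -1 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [-1, 1]")
        for name in ("accessory_fraction", "accessory_prevalence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        n_paired = 2 * (self.n_confounded_pairs + self.n_near_relatives)
        if self.n_confounded_pairs < 0 or self.n_near_relatives < 0:
            raise ValidationError("pair counts must be >= 0")
        if n_paired > self.n_organisms:
            raise ValidationError(
                "too many confounded/relative pairs for the organism count"
            )


@dataclass(frozen=True)
class OrganismTruth:
    organism_id: str
    genes: dict[str, int]  # gene id -> length (nt)
    accessory_genes: frozenset[str]
    otus: dict[str, int]  # otu id -> 16S copy number
    latent: np.ndarray  # latent abundance per sample, > 0
    partner: str | None = None  # paired organism, if any
    partner_relation: str | None = None  # "confounded" | "relative"


@dataclass(frozen=True)
class SyntheticTruth:
    organisms: dict[str, OrganismTruth]

    def mgs_id(self, organism_id: str) -> str:
        return f"MGS_{organism_id}"


class GeneratedCommunity(NamedTuple):
    gene_counts: CountMatrix
    gene_lengths: GeneLengthTable
    membership: MgsMembership
    otu_counts: CountMatrix
    truth: SyntheticTruth


def _latent_abundances(config: CommunityConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent abundance matrix (organisms x samples), log-normal marginals.

    Paired organisms (confounded, then near relatives, taken from the front
    of the organism list) get bivariate-normal log abundances with the
    configured correlation; everyone else is independent.
    """
    n, s = config.n_organisms, config.n_samples
    sigma = config.log_abundance_sigma
    z = rng.standard_normal((n, s))
    pair_rhos = [config.rho_conf] * config.n_confounded_pairs
    pair_rhos += [config.rho_rel] * config.n_near_relatives
    for p, rho in enumerate(pair_rhos):
        i, j = 2 * p, 2 * p + 1
        z[j] = rho * z[i] + np.sqrt(1.0 - rho**2) * z[j]
    return np.exp(sigma * z)


def _poisson_table(
    weights: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts with per-sample rates depth * weights / colsum(weights)."""
    colsums = weights.sum(axis=0)
    safe = np.where(colsums == 0, 1.0, colsums)
    rates = depth * weights / safe
    return rng.poisson(rates)


def generate_community(config: CommunityConfig) -> GeneratedCommunity:
    """Draw one community: gene counts, lengths, membership, OTU counts, truth.

    The draw order is fixed, so identical configs (including the seed) give
    byte-identical outputs.  Expected shotgun column totals equal
    ``shotgun_depth`` (the per-sample rates are normalized before the Poisson
    draw); likewise for the amplicon table.
    """
    rng = np.random.default_rng(config.seed)
    n, s = config.n_organisms, config.n_samples
    latent = _latent_abundances(config, rng)
    rel = latent / latent.sum(axis=0)  # organism relative abundance per sample

    organisms: dict[str, OrganismTruth] = {}
    gene_ids: list[str] = []
    gene_lengths: list[int] = []
    gene_org_row: list[int] = []
    accessory_mask: list[bool] = []
    otu_ids: list[str] = []
    otu_copy: list[int] = []
    otu_org_row: list[int] = []

    pair_relations: dict[int, tuple[int, str]] = {}
    for p in range(config.n_confounded_pairs):
        pair_relations[2 * p] = (2 * p + 1, "confounded")
        pair_relations[2 * p + 1] = (2 * p, "confounded")
    offset = 2 * config.n_confounded_pairs
    for p in range(config.n_near_relatives):
        i, j = offset + 2 * p, offset + 2 * p + 1
        pair_relations[i] = (j, "relative")
        pair_relations[j] = (i, "relative")

    for o in range(n):
        org_id = f"org{o:03d}"
        n_genes = int(rng.integers(config.genes_per_organism[0],
                                   config.genes_per_organism[1] + 1))
        lengths = rng.integers(config.gene_length_range[0],
                               config.gene_length_range[1] + 1, size=n_genes)
        n_accessory = int(round(config.accessory_fraction * n_genes))
        ids = [f"{org_id}_g{i:04d}" for i in range(n_genes)]
        gene_ids.extend(ids)
        gene_lengths.extend(int(x) for x in lengths)
        gene_org_row.extend([o] * n_genes)
        accessory_mask.extend([i < n_accessory for i in range(n_genes)])

        n_otus = int(rng.integers(config.otus_per_organism[0],
                                  config.otus_per_organism[1] + 1))
        copies = rng.integers(1, 8, size=n_otus)  # 16S copy numbers 1-7
        oids = [f"{org_id}_otu{i}" for i in range(n_otus)]
        otu_ids.extend(oids)
        otu_copy.extend(int(c) for c in copies)
        otu_org_row.extend([o] * n_otus)

        partner_row, relation = pair_relations.get(o, (None, None))
        organisms[org_id] = OrganismTruth(
            organism_id=org_id,
            genes=dict(zip(ids, (int(x) for x in lengths))),
            accessory_genes=frozenset(g for g, acc in zip(ids, accessory_mask[-n_genes:])
                                      if acc),
            otus=dict(zip(oids, (int(c) for c in copies))),
            latent=latent[o].copy(),
            partner=f"org{partner_row:03d}" if partner_row is not None else None,
            partner_relation=relation,
        )

    # shotgun gene table: weight = organism rel. abundance x gene length,
    # accessory genes gated by a per-(gene, sample) presence indicator
    length_arr = np.asarray(gene_lengths, dtype=np.float64)
    gene_weights = rel[gene_org_row] * length_arr[:, None]
    acc = np.asarray(accessory_mask)
    if acc.any():
        presence = rng.random((int(acc.sum()), s)) < config.accessory_prevalence
        gene_weights[acc] *= presence
    sample_ids = [f"sample{j:03d}" for j in range(s)]
    gene_counts = _poisson_table(gene_weights, config.shotgun_depth, rng)

    # amplicon OTU table: weight = organism rel. abundance x 16S copy number
    otu_weights = rel[otu_org_row] * np.asarray(otu_copy, dtype=np.float64)[:, None]
    otu_counts = _poisson_table(otu_weights, config.amplicon_depth, rng)

    gene_cm = CountMatrix(pd.DataFrame(gene_counts, index=pd.Index(gene_ids, name="gene_id"),
                                       columns=sample_ids))
    otu_cm = CountMatrix(pd.DataFrame(otu_counts, index=pd.Index(otu_ids, name="otu_id"),
                                      columns=sample_ids))
    lengths_series = pd.Series(np.asarray(gene_lengths, dtype=np.int64),
                               index=pd.Index(gene_ids, name="gene_id"), name="length_nt")
    truth = SyntheticTruth(organisms)
    membership = pd.Series([truth.mgs_id(f"org{o:03d}") for o in gene_org_row],
                           index=pd.Index(gene_ids, name="gene_id"), name="mgs_id")
    return GeneratedCommunity(gene_cm, lengths_series, membership, otu_cm, truth)


def truth_links(truth: SyntheticTruth) -> list[tuple[str, str]]:
    """The answer key: one (otu_id, mgs_id) pair per OTU."""
    pairs = []
    for org in truth.organisms.values():
        mgs = truth.mgs_id(org.organism_id)
        for otu in org.otus:
            pairs.append((otu, mgs))
    return pairs
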