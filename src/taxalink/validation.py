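"""Linking-quality metrics: genus concordance, cutoff calibration, recovery.

Genus-level taxonomy is the correctness proxy used throughout: a link between
an OTU and an MGS is counted correct when both carry a usable genus label and
the labels agree.  Comparison is purely string-based at the genus rank
(case-insensitive, whitespace-stripped); no taxonomy-tree reconciliation is
attempted — disagreements are reported, never rescued.  An entity annotated
by several sources that disagree is treated as unannotated, and RDP labels
below the confidence floor (80% by default) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import AnnotationTable, MgsMembership
from .linking import DEFAULT_CUTOFF, LinkResult

DEFAULT_MIN_RDP_CONFIDENCE = 0.80
DEFAULT_MIN_CLUSTER_FRACTION = 0.70


@dataclass(frozen=True)
class ConcordanceSummary:
    """Genus agreement over a set of passing links."""

    n_links: int
    n_annotated: int  # both sides carry a usable genus
    n_agree: int
    accuracy: float | None  # n_agree / n_annotated; None when undefined


@dataclass(frozen=True)
class CalibrationPoint:
    cutoff: float
    n_passing: int
    n_correct: int
    n_incorrect: int
    accuracy: float | None


@dataclass(frozen=True)
class CalibrationCurve:
    points: tuple[CalibrationPoint, ...]


@dataclass(frozen=True)
class SecondHitSummary:
    n_both_pass: int
    n_both_annotated: int
    n_same_genus: int


@dataclass(frozen=True)
class RecoverySummary:
    precision: float | None
    recall: float
    n_true_pairs: int


def resolve_genus(
    annotations: AnnotationTable,
    min_rdp_confidence: float = DEFAULT_MIN_RDP_CONFIDENCE,
) -> dict[str, str]:
    """Map each entity to its single usable genus label.

    A label is usable iff present and, for RDP annotations, its classification
    confidence reaches ``min_rdp_confidence``.  When multiple sources give
    conflicting genera (case-insensitive) the entity is left unannotated.
    Returned values are whitespace-stripped originals; compare casefolded.
    """
    out: dict[str, str] = {}
    conflicted: set[str] = set()
    for row in annotations.itertuples(index=False):
        genus = row.genus
        if genus is None or (isinstance(genus, float) and np.isnan(genus)):
            continue
        genus = str(genus).strip()
        if not genus:
            continue
        if row.source == "RDP" and row.confidence < min_rdp_confidence:
            continue
        entity = str(row.entity_id)
        if entity in conflicted:
            continue
        prev = out.get(entity)
        if prev is None:
            out[entity] = genus
        elif prev.casefold() != genus.casefold():
            del out[entity]
            conflicted.add(entity)
    return out


def genus_concordance(
    links: list[LinkResult],
    query_annotations: AnnotationTable,
    hit_annotations: AnnotationTable,
    min_rdp_confidence: float = DEFAULT_MIN_RDP_CONFIDENCE,
) -> ConcordanceSummary:
    """Genus agreement between each passing link's query and best hit.

    ``links`` must contain only passing results; a link counts toward the
    accuracy denominator only when both the query and the best hit have a
    usable genus.
    """
    not_passing = [l.query_id for l in links if not l.passes_cutoff]
    if not_passing:
        raise ValidationError(
            f"genus_concordance expects passing links only; offending: {not_passing[:5]}"
        )
    q_genus = resolve_genus(query_annotations, min_rdp_confidence)
    h_genus = resolve_genus(hit_annotations, min_rdp_confidence)
    n_annotated = n_agree = 0
    for link in links:
        if link.best_id is None:
            continue
        qg = q_genus.get(link.query_id)
        hg = h_genus.get(link.best_id)
        if qg is None or hg is None:
            continue
        n_annotated += 1
        if qg.casefold() == hg.casefold():
            n_agree += 1
    accuracy = n_agree / n_annotated if n_annotated else None
    return ConcordanceSummary(len(links), n_annotated, n_agree, accuracy)


def calibrate_cutoff(
    links_with_truth: list[tuple[LinkResult, bool | None]],
    cutoff_grid: list[float],
) -> CalibrationCurve:
    """Accuracy/error tradeoff across candidate correlation cutoffs.

    For each cutoff c, links with best_r >= c are counted as passing; those
    with a known truth flag split into correct/incorrect, and accuracy is
    n_correct / (n_correct + n_incorrect).  The full curve is returned —
    choosing a single operating point is left to the caller (see
    :func:`select_cutoff`).
    """
    if not cutoff_grid:
        raise ValidationError("cutoff grid must be non-empty")
    if sorted(cutoff_grid) != list(cutoff_grid):
        raise ValidationError("cutoff grid must be sorted ascending")
    points = []
    for c in cutoff_grid:
        n_passing = n_correct = n_incorrect = 0
        for link, agree in links_with_truth:
            if link.best_r is None or link.best_r < c:
                continue
            n_passing += 1
            if agree is True:
                n_correct += 1
            elif agree is False:
                n_incorrect += 1
        denom = n_correct + n_incorrect
        accuracy = n_correct / denom if denom else None
        points.append(CalibrationPoint(c, n_passing, n_correct, n_incorrect, accuracy))
    return CalibrationCurve(tuple(points))


def select_cutoff(curve: CalibrationCurve, min_accuracy: float) -> float | None:
    """Smallest cutoff on the curve whose accuracy reaches ``min_accuracy``.

    A convenience rule for picking an operating point from the calibration
    curve; returns None when no cutoff qualifies.
    """
    for p in curve.points:
        if p.accuracy is not None and p.accuracy >= min_accuracy:
            return p.cutoff
    return None


def second_hit_agreement(
    links: list[LinkResult],
    annotations: AnnotationTable,
    cutoff: float = DEFAULT_CUTOFF,
    min_rdp_confidence: float = DEFAULT_MIN_RDP_CONFIDENCE,
) -> SecondHitSummary:
    """How often the second hit corroborates the best hit.

    Counts links where both the best and second correlations reach the
    cutoff; among those, links where both hits carry a usable genus; and
    among those, links where the two genera match.  A best and second hit
    sharing an entity id indicates an undeduplicated candidate list upstream
    and is an error.
    """
    genus = resolve_genus(annotations, min_rdp_confidence)
    n_both_pass = n_both_annotated = n_same = 0
    for link in links:
        if link.second_id is not None and link.second_id == link.best_id:
            raise ValidationError(
                f"query {link.query_id}: best and second hit are the same entity"
            )
        if link.best_r is None or link.second_r is None:
            continue
        if link.best_r < cutoff or link.second_r < cutoff:
            continue
        n_both_pass += 1
        bg = genus.get(link.best_id)
        sg = genus.get(link.second_id)
        if bg is None or sg is None:
            continue
        n_both_annotated += 1
        if bg.casefold() == sg.casefold():
            n_same += 1
    return SecondHitSummary(n_both_pass, n_both_annotated, n_same)


def assign_cluster_to_mgs(
    cluster_genes: set[str],
    membership: MgsMembership,
    min_fraction: float = DEFAULT_MIN_CLUSTER_FRACTION,
) -> str | None:
    """Assign a gene cluster to the MGS holding >= ``min_fraction`` of it.

    f(m) = |cluster ∩ genes(m)| / |cluster|; the argmax MGS is returned iff
    f reaches the floor (inclusive).  A tie at the maximum is ambiguous and
    yields None.
    """
    if not cluster_genes:
        raise ValidationError("cluster must be non-empty")
    cluster = set(str(g) for g in cluster_genes)
    present = membership.reindex(sorted(cluster)).dropna()
    if present.empty:
        return None
    counts = present.groupby(present).size()
    top = counts.max()
    if top / len(cluster) < min_fraction:
        return None
    winners = counts[counts == top]
    if len(winners) > 1:
        return None  # ambiguous
    return str(winners.index[0])


def evaluate_recovery(links: list[LinkResult], truth) -> RecoverySummary:
    """Score passing links against the synthetic answer key.

    ``truth`` is a SyntheticTruth; a passing link is correct iff its best hit
    is the MGS of the same ground-truth organism as the query OTU.  OTUs that
    never produced a passing link (including those removed by the prevalence
    filter) count as unrecovered: recall is correct / n_true_pairs over all
    truth pairs.
    """
    from .synthetic_data import truth_links  # local import avoids a cycle

    expected = dict(truth_links(truth))
    n_true_pairs = len(expected)
    passing = [l for l in links if l.passes_cutoff and l.best_id is not None]
    n_correct = sum(1 for l in passing if expected.get(l.query_id) == l.best_id)
    precision = n_correct / len(passing) if passing else None
    recall = n_correct / n_true_pairs if n_true_pairs else 0.0
    return RecoverySummary(precision, recall, n_true_pairs)
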