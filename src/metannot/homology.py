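"""Confidence scoring of Swiss-Prot homologs for annotation transfer.

Each BLAST hit against Swiss-Prot is scored on a 0-12 point rubric that
combines the e-value, the sequence identity (only counted when the
alignment covers more than 40% of both sequences), the mutual alignment
coverage, and reciprocal-best-hit status in both search directions — a
classic orthology proxy.  Totals of at least 10, 8 and 6 points map to the
confidence tiers 'very confident', 'confident' and 'probable'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .iofmt import Collection, HitRecord, ValidationError

EVALUE_CUTOFF = 1e-3


class Tier(str, Enum):
    VERY_CONFIDENT = "very confident"
    CONFIDENT = "confident"
    PROBABLE = "probable"
    UNASSIGNED = "unassigned"


class Direction(str, Enum):
    FORWARD = "FORWARD"  # query searched against the hit's proteome
    REVERSE = "REVERSE"  # hit searched against the query's proteome


class RbhStatus(str, Enum):
    BEST = "BEST"
    NOT_BEST = "NOT_BEST"
    UNAVAILABLE = "UNAVAILABLE"


@dataclass(frozen=True)
class ReciprocalStatus:
    direction: Direction
    status: RbhStatus


@dataclass(frozen=True)
class TierScheme:
    """Point thresholds for the three confidence tiers."""

    very: float
    confident: float
    probable: float

    def __post_init__(self) -> None:
        if not (self.very > self.confident > self.probable >= 0):
            raise ValidationError("tier thresholds must be strictly decreasing")


HOMOLOG_TIERS = TierScheme(very=10, confident=8, probable=6)


def assign_tier(total: float, scheme: TierScheme = HOMOLOG_TIERS) -> Tier:
    if total >= scheme.very:
        return Tier.VERY_CONFIDENT
    if total >= scheme.confident:
        return Tier.CONFIDENT
    if total >= scheme.probable:
        return Tier.PROBABLE
    return Tier.UNASSIGNED


@dataclass(frozen=True)
class HomologScore:
    points_evalue: int
    points_identity: int
    points_coverage: int
    points_forward: int
    points_reverse: int
    total: int
    tier: Tier


def _identity_points(identity: float, q_cov: float, s_cov: float) -> int:
    # identity only informative when the alignment spans both sequences
    if min(q_cov, s_cov) <= 40.0:
        return 0
    if identity > 99.0:
        return 5
    if identity >= 90.0:
        return 4
    if identity >= 70.0:
        return 3
    if identity >= 50.0:
        return 2
    if identity >= 30.0:
        return 1
    return 0


def _coverage_points(q_cov: float, s_cov: float) -> int:
    both = min(q_cov, s_cov)
    if both >= 80.0:
        return 2
    if both >= 60.0:
        return 1
    return 0


_RBH_POINTS = {RbhStatus.BEST: 2, RbhStatus.UNAVAILABLE: 1, RbhStatus.NOT_BEST: 0}


def score_homolog(hit: HitRecord, fwd: ReciprocalStatus, rev: ReciprocalStatus,
                  scheme: TierScheme = HOMOLOG_TIERS) -> HomologScore:
    """Apply the 0-12 point homolog rubric to one Swiss-Prot hit."""
    if hit.collection != Collection.SPROT:
        raise ValidationError(
            f"homolog scoring requires a Swiss-Prot hit, got {hit.collection.value}")
    p_eval = 1 if (hit.evalue is not None and hit.evalue < EVALUE_CUTOFF) else 0
    p_id = _identity_points(hit.identity_pct, hit.q_cov_pct, hit.s_cov_pct)
    p_cov = _coverage_points(hit.q_cov_pct, hit.s_cov_pct)
    p_fwd = _RBH_POINTS[fwd.status]
    p_rev = _RBH_POINTS[rev.status]
    total = p_eval + p_id + p_cov + p_fwd + p_rev
    return HomologScore(p_eval, p_id, p_cov, p_fwd, p_rev, total,
                        assign_tier(total, scheme))


def reciprocal_status(
    query_id: str,
    hit_id: str,
    forward_hits: Optional[list[HitRecord]],
    reverse_hits: Optional[list[HitRecord]],
) -> tuple[ReciprocalStatus, ReciprocalStatus]:
    """Reciprocal-best-hit status from the two proteome search tables.

    ``forward_hits`` ranks the query against the hit organism's proteome;
    the hit is BEST when it is rank 1.  ``reverse_hits`` ranks the hit
    against the query organism's proteome; the query is BEST when it is
    rank 1.  An absent table yields UNAVAILABLE for that direction.
    Tables must be sorted by ascending e-value.
    """
    def status(table: Optional[list[HitRecord]], wanted: str) -> RbhStatus:
        if table is None:
            return RbhStatus.UNAVAILABLE
        if table and table[0].subject_id == wanted:
            return RbhStatus.BEST
        return RbhStatus.NOT_BEST

    return (
        ReciprocalStatus(Direction.FORWARD, status(forward_hits, hit_id)),
        ReciprocalStatus(Direction.REVERSE, status(reverse_hits, query_id)),
    )


@dataclass(frozen=True)
class RankedHomolog:
    """One scored annotation-transfer candidate as it appears in the report."""

    subject_id: str
    annotation: str
    evalue: float
    identity_pct: float
    score: HomologScore
    ec_numbers: tuple = ()
    go_terms: tuple = ()


def top_homologs(scored: list[RankedHomolog], n: int = 10) -> list[RankedHomolog]:
    """The n closest confident homologs (e-value below the 0.001 cutoff).

    Sorted by total points (desc), then e-value (asc), then subject id.
    """
    confident = [h for h in scored if h.evalue < EVALUE_CUTOFF]
    confident.sort(key=lambda h: (-h.score.total, h.evalue, h.subject_id))
    return confident[:n]


def score_sprot_hits(
    query_id: str,
    hits: list[HitRecord],
    forward_hits: Optional[list[HitRecord]] = None,
    reverse_tables: Optional[dict[str, list[HitRecord]]] = None,
    scheme: TierScheme = HOMOLOG_TIERS,
) -> list[RankedHomolog]:
    """Score every Swiss-Prot hit, wiring in per-hit reciprocal tables."""
    out = []
    for hit in hits:
        reverse = None if reverse_tables is None else reverse_tables.get(
            hit.subject_id)
        fwd, rev = reciprocal_status(query_id, hit.subject_id,
                                     forward_hits, reverse)
        score = score_homolog(hit, fwd, rev, scheme)
        out.append(RankedHomolog(
            subject_id=hit.subject_id,
            annotation=hit.annotation,
            evalue=hit.evalue if hit.evalue is not None else float("inf"),
            identity_pct=hit.identity_pct,
            score=score,
            ec_numbers=hit.ec_numbers,
            go_terms=hit.go_terms,
        ))
    return out
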