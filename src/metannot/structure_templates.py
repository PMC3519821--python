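"""Scoring and greedy selection of homology-modeling templates.

Structure templates are detected by three routes — BLAST against the PDB
(e-value <= 0.001), RPS-BLAST against structure-domain profiles
(e-value <= 0.01), and a profile-profile search (probability >= 80%).
Each template is scored on sequence identity, the profile-search
probability, the sequence-search e-value, and a cross-method consensus
bonus.  Templates are then scanned from the top of the ranking and kept
only when they cover at least 30 query residues not covered by any
higher-ranked accepted template, yielding a non-redundant set whose joint
residue coverage summarizes how much of the query is modelable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .feature_consensus import ConsensusTrack
from .homology import Tier
from .iofmt import Feature, HitRecord, Method, ValidationError

#: per-method detection cutoffs applied before scoring
DETECTION_CUTS = {
    Method.BLAST: ("evalue", 1e-3),
    Method.RPSBLAST: ("evalue", 1e-2),
    Method.HHPRED: ("probability", 80.0),
}

MIN_NEW_RESIDUES = 30
HIGH_COVERAGE_CUT = 0.80


@dataclass(frozen=True)
class TemplateScore:
    template_id: str
    method_set: frozenset  # subset of Method
    points_identity: int
    points_probability: int
    points_evalue: int
    points_consensus: int
    total: int
    q_range: tuple  # merged 1-based inclusive (start, end) intervals
    best_evalue: Optional[float] = None
    best_probability: Optional[float] = None
    tier: Tier = Tier.PROBABLE


@dataclass
class CoverageMask:
    covered: np.ndarray  # bool, length = query length

    @property
    def count(self) -> int:
        return int(self.covered.sum())


@dataclass
class SelectionResult:
    selected: list  # TemplateScore, in acceptance order
    mask: CoverageMask
    fraction_covered: float


def _identity_points(identity: float) -> int:
    if identity >= 90.0:
        return 5
    if identity >= 80.0:
        return 4
    if identity >= 60.0:
        return 3
    if identity >= 40.0:
        return 2
    if identity >= 20.0:
        return 1
    return 0


def _probability_points(prob: float) -> int:
    if prob >= 99.99:
        return 5
    if prob >= 99.0:
        return 4
    if prob >= 90.0:
        return 3
    if prob >= 85.0:
        return 2
    if prob >= 80.0:
        return 1
    return 0


def _evalue_points(evalue: float) -> int:
    # disjoint bins, monotone in significance
    if evalue <= 1e-54:
        return 4
    if evalue <= 1e-18:
        return 3
    if evalue <= 1e-6:
        return 2
    if evalue <= 1e-2:
        return 1
    return 0


def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((a, b) for a, b in merged)


def _template_tier(best_evalue: Optional[float],
                   best_probability: Optional[float]) -> Tier:
    # summary-page labels; thresholds follow the confident-template
    # criteria used in practice, tightened one bin for 'very confident'
    if ((best_probability is not None and best_probability >= 99.0)
            or (best_evalue is not None and best_evalue <= 1e-18)):
        return Tier.VERY_CONFIDENT
    if ((best_probability is not None and best_probability >= 90.0)
            or (best_evalue is not None and best_evalue <= 1e-6)):
        return Tier.CONFIDENT
    return Tier.PROBABLE


def passes_detection(hit: HitRecord) -> bool:
    kind, cut = DETECTION_CUTS[hit.method]
    if kind == "evalue":
        return hit.evalue is not None and hit.evalue <= cut
    return hit.probability_pct is not None and hit.probability_pct >= cut


def score_template(hits: list[HitRecord]) -> TemplateScore:
    """Apply the template rubric to all hits sharing one template id."""
    if not hits:
        raise ValidationError("cannot score a template without hits")
    template_id = hits[0].subject_id
    if any(h.subject_id != template_id for h in hits):
        raise ValidationError("hits for one template must share subject_id")
    methods = frozenset(h.method for h in hits)
    p_id = _identity_points(max(h.identity_pct for h in hits))
    hh = [h.probability_pct for h in hits
          if h.method == Method.HHPRED and h.probability_pct is not None]
    best_prob = max(hh) if hh else None
    p_prob = _probability_points(best_prob) if best_prob is not None else 0
    ev = [h.evalue for h in hits
          if h.method in (Method.BLAST, Method.RPSBLAST) and h.evalue is not None]
    best_ev = min(ev) if ev else None
    p_ev = _evalue_points(best_ev) if best_ev is not None else 0
    p_cons = {1: 0, 2: 1, 3: 2}[len(methods)]
    total = p_id + p_prob + p_ev + p_cons
    q_range = _merge_intervals([(h.q_start, h.q_end) for h in hits])
    return TemplateScore(template_id, methods, p_id, p_prob, p_ev, p_cons,
                         total, q_range, best_ev, best_prob,
                         _template_tier(best_ev, best_prob))


def rank_templates(scores: list[TemplateScore]) -> list[TemplateScore]:
    """Rubric total desc, then e-value asc, probability desc, id asc."""
    return sorted(scores, key=lambda t: (
        -t.total,
        t.best_evalue if t.best_evalue is not None else float("inf"),
        -(t.best_probability if t.best_probability is not None else 0.0),
        t.template_id,
    ))


def score_template_hits(hits: list[HitRecord]) -> list[TemplateScore]:
    """Filter hits by the detection cuts, group per template, score, rank."""
    grouped: dict[str, list[HitRecord]] = {}
    for hit in hits:
        if passes_detection(hit):
            grouped.setdefault(hit.subject_id, []).append(hit)
    return rank_templates([score_template(g) for g in grouped.values()])


def select_nonredundant(ranked: list[TemplateScore], query_length: int,
                        min_new: int = MIN_NEW_RESIDUES) -> SelectionResult:
    """Greedy scan keeping templates that add >= min_new uncovered residues.

    The rule applies to every template including the first: a template
    spanning fewer than min_new residues is uninformative for modeling.
    """
    if min_new < 1:
        raise ValidationError("min_new must be at least 1")
    covered = np.zeros(query_length, dtype=bool)
    selected = []
    for t in ranked:
        idx = np.concatenate([np.arange(a - 1, b) for a, b in t.q_range]) \
            if t.q_range else np.array([], dtype=int)
        idx = idx[idx < query_length]
        new = int((~covered[idx]).sum())
        if new >= min_new:
            covered[idx] = True
            selected.append(t)
    mask = CoverageMask(covered)
    fraction = mask.count / query_length if query_length else 0.0
    return SelectionResult(selected, mask, fraction)


def coverage_stats(selection: SelectionResult,
                   disorder: Optional[ConsensusTrack] = None
                   ) -> tuple[float, float, bool]:
    """Residue-coverage summary of the selected template set.

    Returns the fraction of residues covered by templates, the fraction
    covered or called disordered by the consensus (disordered residues are
    not expected to be modelable), and whether the combined fraction
    exceeds the 80% high-coverage mark.
    """
    covered = selection.mask.covered
    length = covered.size
    if disorder is not None:
        if disorder.feature != Feature.DISORDER:
            raise ValidationError("coverage_stats expects the DISORDER consensus")
        if len(disorder.symbols) != length:
            raise ValidationError("disorder track length differs from query length")
        dis = np.frombuffer(disorder.symbols.encode(), dtype="S1") == b"*"
        combined = covered | dis
    else:
        combined = covered
    f_cov = float(covered.sum()) / length if length else 0.0
    f_comb = float(combined.sum()) / length if length else 0.0
    return f_cov, f_comb, f_comb > HIGH_COVERAGE_CUT
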