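"""Confidence scoring and hierarchical propagation of GO terms.

Candidate GO terms come from annotated homologs.  A term's score combines
how similar the supporting hit is to the query (e-value, identity,
coverage — the same criteria used for homologs), the strength of the
evidence code under which the term was assigned to the hit (experimental
codes outrank electronic ones), and a consensus bonus when at least three
distinct hits carry the term; totals run 0-12 with tiers at 10/8/6.

Because the Gene Ontology is a hierarchy, assigning a term implies all of
its ancestors: each ancestor receives the highest score among its scored
descendants (or its own direct score, whichever is larger).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .homology import HOMOLOG_TIERS, Tier, TierScheme, assign_tier
from .iofmt import HitRecord, ValidationError

EVALUE_CUTOFF = 1e-3

#: points per GO evidence code; experimental > curated > electronic
EVIDENCE_POINTS = {
    **{c: 3 for c in ("EXP", "IDA")},
    **{c: 2 for c in ("IPI", "IMP", "IGI", "IEP", "ISO", "TAS")},
    **{c: 1 for c in ("ISS", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR",
                      "IRD", "RCA", "NAS", "IC", "IEA")},
}

CONSENSUS_BONUS = 2
CONSENSUS_MIN_HITS = 3


@dataclass(frozen=True)
class GoHierarchy:
    """Parent edges of the ontology fragment relevant to the query."""

    edges: frozenset  # (child_term, parent_term) pairs

    @property
    def terms(self) -> set[str]:
        return {t for edge in self.edges for t in edge}

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)  # child -> parent
        return g


@dataclass(frozen=True)
class GoTermScore:
    term: str
    points_evalue: int
    points_identity: int
    points_coverage: int
    points_evidence: int
    points_consensus: int
    total: int
    tier: Tier
    supporting_hits: tuple = ()
    propagated_from: Optional[str] = None


def _identity_points(identity: float, q_cov: float, s_cov: float) -> int:
    if min(q_cov, s_cov) <= 40.0:
        return 0
    if identity >= 90.0:
        return 4  # top identity bin for GO transfer is 90-100%
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


def score_go_term(term: str,
                  supporting: list[tuple[HitRecord, str]],
                  scheme: TierScheme = HOMOLOG_TIERS) -> GoTermScore:
    """Score one candidate term from its supporting (hit, evidence) pairs.

    The term base is the best per-hit score; the consensus bonus is added
    when the term is carried by at least three distinct subject ids.
    """
    if not supporting:
        raise ValidationError(f"term {term}: no supporting hits")
    best = None
    for hit, code in supporting:
        p_eval = 1 if (hit.evalue is not None and hit.evalue < EVALUE_CUTOFF) else 0
        p_id = _identity_points(hit.identity_pct, hit.q_cov_pct, hit.s_cov_pct)
        p_cov = _coverage_points(hit.q_cov_pct, hit.s_cov_pct)
        p_ev = EVIDENCE_POINTS.get(code, 0)
        base = p_eval + p_id + p_cov + p_ev
        key = (base, -(hit.evalue or 0.0), hit.subject_id)
        if best is None or key > best[0]:
            best = (key, (p_eval, p_id, p_cov, p_ev))
    p_eval, p_id, p_cov, p_ev = best[1]
    distinct = {hit.subject_id for hit, _ in supporting}
    p_cons = CONSENSUS_BONUS if len(distinct) >= CONSENSUS_MIN_HITS else 0
    total = p_eval + p_id + p_cov + p_ev + p_cons
    return GoTermScore(term, p_eval, p_id, p_cov, p_ev, p_cons, total,
                       assign_tier(total, scheme),
                       supporting_hits=tuple(sorted(distinct)))


def collect_go_candidates(hits: list[HitRecord],
                          scheme: TierScheme = HOMOLOG_TIERS
                          ) -> dict[str, GoTermScore]:
    """Group the annotated hits by GO term and score every candidate."""
    by_term: dict[str, list[tuple[HitRecord, str]]] = {}
    for hit in hits:
        for term, code in hit.go_terms:
            by_term.setdefault(term, []).append((hit, code))
    return {term: score_go_term(term, support, scheme)
            for term, support in sorted(by_term.items())}


def propagate_parents(scores: dict[str, GoTermScore],
                      hierarchy: GoHierarchy,
                      scheme: TierScheme = HOMOLOG_TIERS
                      ) -> dict[str, GoTermScore]:
    """Push every score up the ontology: ancestors take the descendant max.

    A term keeps its own direct score when that is at least as high as any
    descendant's; otherwise it inherits the best descendant's score (and
    records which descendant it came from).  Idempotent by construction.
    """
    graph = hierarchy.graph()
    if not nx.is_directed_acyclic_graph(graph):
        raise ValidationError("GO hierarchy contains a cycle")
    out = dict(scores)
    for term, score in scores.items():
        if term not in graph:
            continue
        source = score.propagated_from or term
        for ancestor in nx.descendants(graph, term):  # edges point child->parent
            current = out.get(ancestor)
            inherited = GoTermScore(
                term=ancestor,
                points_evalue=score.points_evalue,
                points_identity=score.points_identity,
                points_coverage=score.points_coverage,
                points_evidence=score.points_evidence,
                points_consensus=score.points_consensus,
                total=score.total,
                tier=assign_tier(score.total, scheme),
                supporting_hits=score.supporting_hits,
                propagated_from=source,
            )
            if current is None:
                out[ancestor] = inherited
            elif score.total > current.total:
                out[ancestor] = inherited
            elif (score.total == current.total
                  and current.propagated_from is not None
                  and source < current.propagated_from):
                out[ancestor] = inherited  # deterministic tie on equal totals
    return out


def rank_go_predictions(scores: dict[str, GoTermScore],
                        scheme: TierScheme = HOMOLOG_TIERS
                        ) -> list[GoTermScore]:
    """Reportable predictions: at least 'probable', best first."""
    kept = [s for s in scores.values() if s.total >= scheme.probable]
    kept.sort(key=lambda s: (-s.total, s.term))
    return kept
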