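"""Template rubric, greedy non-redundant selection, and coverage stats."""

import itertools
import random

import numpy as np
import pytest

from metannot.feature_consensus import ConsensusTrack
from metannot.iofmt import Collection, Feature, HitRecord, Method, ValidationError
from metannot.structure_templates import (
    SelectionResult,
    TemplateScore,
    coverage_stats,
    passes_detection,
    rank_templates,
    score_template,
    score_template_hits,
    select_nonredundant,
)


def _hit(tid="1abcA", method=Method.BLAST, q_start=1, q_end=100,
         identity=40.0, evalue=None, prob=None):
    return HitRecord(tid, Collection.PDB, method, q_start, q_end, 1,
                     q_end - q_start + 1, identity_pct=identity,
                     q_cov_pct=50.0, s_cov_pct=50.0, evalue=evalue,
                     probability_pct=prob)


class TestScoreTemplate:
    def test_hhpred_only_hit(self):
        s = score_template([_hit(method=Method.HHPRED, identity=30.0,
                                 prob=99.5)])
        assert (s.points_identity, s.points_probability) == (1, 4)
        assert s.total == 5

    def test_three_method_consensus_bonus(self):
        hits = [_hit(method=Method.BLAST, evalue=1e-10),
                _hit(method=Method.RPSBLAST, evalue=1e-5),
                _hit(method=Method.HHPRED, prob=95.0)]
        assert score_template(hits).points_consensus == 2

    def test_blast_only_weak_identity(self):
        s = score_template([_hit(identity=15.0, evalue=1e-3)])
        assert s.total == 1  # e-value bin only; identity below 20 scores 0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValidationError):
            score_template([])

    def test_mixed_template_ids_rejected(self):
        with pytest.raises(ValidationError):
            score_template([_hit("A", evalue=1e-4), _hit("B", evalue=1e-4)])

    def test_multiple_hsps_merge_into_interval_union(self):
        hits = [_hit(q_start=1, q_end=50, evalue=1e-10),
                _hit(q_start=40, q_end=90, evalue=1e-12),
                _hit(q_start=120, q_end=150, evalue=1e-9)]
        assert score_template(hits).q_range == ((1, 90), (120, 150))

    @pytest.mark.parametrize("evalue,points", [
        (1e-2, 1), (1e-6, 2), (1e-7, 2), (1e-18, 3), (1e-19, 3),
        (1e-54, 4), (1e-60, 4), (0.5, 0)])
    def test_evalue_bins_are_disjoint_and_monotone(self, evalue, points):
        s = score_template([_hit(identity=10.0, evalue=evalue)])
        assert s.points_evalue == points

    @pytest.mark.parametrize("prob,points", [
        (80.0, 1), (85.0, 2), (90.0, 3), (99.0, 4), (99.99, 5), (100.0, 5)])
    def test_probability_bins(self, prob, points):
        s = score_template([_hit(method=Method.HHPRED, identity=10.0,
                                 prob=prob)])
        assert s.points_probability == points

    def test_rubric_ceiling_is_sixteen(self):
        """Exhaustive bin scan: 5 (identity) + 5 (prob) + 4 (e) + 2 = 16."""
        identities = [10.0, 30.0, 50.0, 70.0, 85.0, 95.0]
        evalues = [1e-3, 1e-10, 1e-30, 1e-60]
        probs = [82.0, 87.0, 95.0, 99.5, 99.999]
        totals = set()
        for ident, e, p in itertools.product(identities, evalues, probs):
            hits = [_hit(method=Method.BLAST, identity=ident, evalue=e),
                    _hit(method=Method.RPSBLAST, identity=ident, evalue=e),
                    _hit(method=Method.HHPRED, identity=ident, prob=p)]
            totals.add(score_template(hits).total)
        assert max(totals) == 16

    def test_detection_cuts_per_method(self):
        assert passes_detection(_hit(method=Method.BLAST, evalue=1e-3))
        assert not passes_detection(_hit(method=Method.BLAST, evalue=2e-3))
        assert passes_detection(_hit(method=Method.RPSBLAST, evalue=1e-2))
        assert not passes_detection(_hit(method=Method.RPSBLAST, evalue=2e-2))
        assert passes_detection(_hit(method=Method.HHPRED, prob=80.0))
        assert not passes_detection(_hit(method=Method.HHPRED, prob=79.9))


def _ts(tid, total, ranges, evalue=1e-10):
    return TemplateScore(tid, frozenset({Method.BLAST}), 0, 0, 0, 0, total,
                         tuple(ranges), best_evalue=evalue)


def greedy_reference(ranked, length, min_new):
    """Independently coded step-by-step selection oracle (set-based)."""
    covered = set()
    selected = []
    for t in ranked:
        residues = set()
        for a, b in t.q_range:
            residues |= set(range(a, min(b, length) + 1))
        if len(residues - covered) >= min_new:
            covered |= residues
            selected.append(t.template_id)
    return selected, covered


class TestSelection:
    def test_exactly_thirty_new_residues_accepted(self):
        ranked = [_ts("A", 10, [(1, 100)]), _ts("B", 8, [(80, 130)])]
        result = select_nonredundant(ranked, 200)
        assert [t.template_id for t in result.selected] == ["A", "B"]

    def test_twenty_nine_new_residues_rejected(self):
        ranked = [_ts("A", 10, [(1, 100)]), _ts("B", 8, [(80, 129)])]
        result = select_nonredundant(ranked, 200)
        assert [t.template_id for t in result.selected] == ["A"]

    def test_first_template_also_needs_thirty(self):
        result = select_nonredundant([_ts("A", 10, [(1, 29)])], 100)
        assert result.selected == [] and result.fraction_covered == 0.0

    def test_empty_input(self):
        result = select_nonredundant([], 100)
        assert result.selected == [] and result.fraction_covered == 0.0

    def test_min_new_below_one_rejected(self):
        with pytest.raises(ValidationError):
            select_nonredundant([], 100, min_new=0)

    def test_selection_monotone_in_min_new(self):
        ranked = [_ts("A", 10, [(1, 100)]), _ts("B", 8, [(90, 140)]),
                  _ts("C", 6, [(130, 160)])]
        loose = select_nonredundant(ranked, 200, min_new=1)
        strict = select_nonredundant(ranked, 200, min_new=40)
        assert len(loose.selected) >= len(strict.selected)

    def test_matches_reference_on_random_instances(self):
        rng = random.Random(20240917)
        for _ in range(1000):
            length = rng.randint(40, 300)
            templates = []
            for k in range(rng.randint(0, 12)):
                n_ivl = rng.randint(1, 3)
                ivls = []
                for _ in range(n_ivl):
                    a = rng.randint(1, length)
                    b = min(length, a + rng.randint(0, length // 2))
                    ivls.append((a, b))
                merged = []
                for a, b in sorted(ivls):
                    if merged and a <= merged[-1][1] + 1:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], b))
                    else:
                        merged.append((a, b))
                templates.append(_ts(f"T{k:02d}", rng.randint(1, 16), merged,
                                     evalue=10.0 ** -rng.randint(3, 60)))
            ranked = rank_templates(templates)
            result = select_nonredundant(ranked, length)
            ref_ids, ref_cov = greedy_reference(ranked, length, 30)
            assert [t.template_id for t in result.selected] == ref_ids
            got_cov = {i + 1 for i in np.flatnonzero(result.mask.covered)}
            assert got_cov == ref_cov
            # every accepted template after the first added >= 30 residues
            seen = set()
            for t in result.selected:
                residues = set()
                for a, b in t.q_range:
                    residues |= set(range(a, min(b, length) + 1))
                assert len(residues - seen) >= 30
                seen |= residues
            assert 0.0 <= result.fraction_covered <= 1.0


class TestCoverageStats:
    def _selection(self, covered_idx, length):
        mask = np.zeros(length, dtype=bool)
        mask[covered_idx] = True
        from metannot.structure_templates import CoverageMask
        return SelectionResult([], CoverageMask(mask),
                               float(mask.sum()) / length)

    def test_disorder_extends_coverage(self):
        sel = self._selection(np.arange(150), 200)
        disorder = ConsensusTrack(Feature.DISORDER,
                                  "." * 150 + "*" * 20 + "." * 30)
        f_cov, f_comb, high = coverage_stats(sel, disorder)
        assert (f_cov, f_comb, high) == (0.75, 0.85, True)

    def test_full_mask(self):
        sel = self._selection(np.arange(100), 100)
        assert coverage_stats(sel, None) == (1.0, 1.0, True)

    def test_empty_mask_no_disorder(self):
        sel = self._selection([], 100)
        disorder = ConsensusTrack(Feature.DISORDER, "." * 100)
        assert coverage_stats(sel, disorder) == (0.0, 0.0, False)

    def test_length_mismatch_rejected(self):
        sel = self._selection([], 100)
        with pytest.raises(ValidationError):
            coverage_stats(sel, ConsensusTrack(Feature.DISORDER, "." * 90))

    def test_wrong_feature_rejected(self):
        sel = self._selection([], 100)
        with pytest.raises(ValidationError):
            coverage_stats(sel, ConsensusTrack(Feature.TM, "." * 100))
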