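"""Voting, conflict resolution, and conservation indexing."""

import math
import random
from collections import Counter

import pytest
from hypothesis import given, strategies as st

from metannot.feature_consensus import (
    ConsensusTrack,
    VoteConfig,
    consensus_binary,
    consensus_ss3,
    conservation_track,
    profile_filter,
    resolve_sp_tm,
)
from metannot.iofmt import (
    Collection,
    Feature,
    HitRecord,
    Method,
    PredictionTrack,
    QuerySequence,
    ValidationError,
)


def _track(predictor, feature, symbols):
    return PredictionTrack(predictor, feature, symbols)


def _hit(q_cov, identity):
    return HitRecord("h", Collection.NR, Method.BLAST, 1, 50, 1, 50,
                     identity_pct=identity, q_cov_pct=q_cov, s_cov_pct=q_cov,
                     evalue=1e-10)


def brute_force_ss3(tracks, config):
    """Independent per-residue tally, reimplemented from the voting rule."""
    length = len(tracks[0].symbols)
    out = []
    for i in range(length):
        tally = Counter()
        for t in tracks:
            if t.symbols[i] != ".":
                tally[t.symbols[i]] += config.weight(t.predictor)
        if not tally:
            out.append("C")
            continue
        best = max(tally.values())
        leaders = sorted(s for s, v in tally.items() if v == best)
        if len(leaders) == 1:
            out.append(leaders[0])
            continue
        heavy = [t.symbols[i] for t in sorted(
            tracks, key=lambda t: (-config.weight(t.predictor), t.predictor))
            if config.weight(t.predictor) > 1 and t.symbols[i] in leaders]
        if heavy:
            out.append(heavy[0])
        elif "C" in leaders:
            out.append("C")
        else:
            out.append(leaders[0])
    return "".join(out)


class TestSs3Voting:
    def test_double_weighted_predictor_beats_single(self):
        tracks = [_track("PSIPRED", Feature.SS3, "H"),
                  _track("SSPRO", Feature.SS3, "E")]
        assert consensus_ss3(tracks).symbols == "H"

    def test_unanimous_coil(self):
        tracks = [_track("PSIPRED", Feature.SS3, "CC"),
                  _track("SSPRO", Feature.SS3, "CC")]
        result = consensus_ss3(tracks)
        assert result.symbols == "CC"
        assert result.tallies[0] == {"C": 3}

    def test_coil_voter_loses_to_helix_majority(self):
        tracks = [_track("PSIPRED", Feature.SS3, "H"),
                  _track("SSPRO", Feature.SS3, "H"),
                  _track("DISEMBL-coils", Feature.SS3, "C")]
        assert consensus_ss3(tracks).symbols == "H"  # 3 votes vs 1

    def test_no_tracks_is_an_error(self):
        with pytest.raises(ValidationError):
            consensus_ss3([])

    @given(st.data())
    def test_matches_brute_force_tally(self, data):
        n_tracks = data.draw(st.integers(2, 6))
        length = data.draw(st.integers(1, 25))
        names = [f"P{i}" for i in range(n_tracks)]
        weights = {n: data.draw(st.integers(1, 2)) for n in names}
        tracks = [
            _track(n, Feature.SS3,
                   "".join(data.draw(st.sampled_from("HEC."))
                           for _ in range(length)))
            for n in names]
        config = VoteConfig(weights=weights)
        assert consensus_ss3(tracks, config).symbols == \
            brute_force_ss3(tracks, config)

    @given(st.permutations(range(4)), st.integers(0, 2 ** 30))
    def test_permutation_invariant(self, order, seed):
        rng = random.Random(seed)
        tracks = [_track(f"P{i}", Feature.SS3,
                         "".join(rng.choice("HEC") for _ in range(15)))
                  for i in range(4)]
        shuffled = [tracks[i] for i in order]
        assert consensus_ss3(tracks).symbols == consensus_ss3(shuffled).symbols

    @given(st.integers(0, 2 ** 30))
    def test_agreeing_predictor_never_flips_calls(self, seed):
        rng = random.Random(seed)
        tracks = [_track(f"P{i}", Feature.SS3,
                         "".join(rng.choice("HEC") for _ in range(20)))
                  for i in range(3)]
        before = consensus_ss3(tracks).symbols
        tracks.append(_track("AGREE", Feature.SS3, before))
        assert consensus_ss3(tracks).symbols == before


class TestBinaryVoting:
    def test_disorder_two_of_four_is_positive(self):
        tracks = [_track(p, Feature.DISORDER, s) for p, s in [
            ("DISPRO", "*"), ("DISOPRED", "*"),
            ("IsUnstruct", "."), ("DISEMBL-missing", ".")]]
        assert consensus_binary(tracks, Feature.DISORDER).symbols == "*"

    def test_signal_phobius_alone_is_not_enough(self):
        tracks = [_track("Phobius", Feature.SIGNAL, "S"),
                  _track("SignalP-HMM", Feature.SIGNAL, "."),
                  _track("SignalP-NN", Feature.SIGNAL, "."),
                  _track("MEMSATSVM", Feature.SIGNAL, ".")]
        # Phobius carries 2 of the 5 votes; the threshold is 3
        assert consensus_binary(tracks, Feature.SIGNAL).symbols == "."

    def test_signal_phobius_plus_one_is_enough(self):
        tracks = [_track("Phobius", Feature.SIGNAL, "S"),
                  _track("SignalP-HMM", Feature.SIGNAL, "S"),
                  _track("SignalP-NN", Feature.SIGNAL, "."),
                  _track("MEMSATSVM", Feature.SIGNAL, ".")]
        assert consensus_binary(tracks, Feature.SIGNAL).symbols == "S"

    def test_all_negative_stays_negative(self):
        tracks = [_track(f"P{i}", Feature.TM, "..") for i in range(3)]
        assert consensus_binary(tracks, Feature.TM).symbols == ".."

    def test_tm_needs_strict_majority_of_contributed_votes(self):
        tracks = [_track(p, Feature.TM, s) for p, s in [
            ("TMHMM", "H"), ("HMMTOP", "H"), ("MEMSAT", ".")]]
        # 2 of 3 votes is a strict majority
        assert consensus_binary(tracks, Feature.TM).symbols == "H"
        tracks[1] = _track("HMMTOP", Feature.TM, ".")
        assert consensus_binary(tracks, Feature.TM).symbols == "."

    @given(st.integers(0, 2 ** 30))
    def test_matches_brute_force_threshold(self, seed):
        rng = random.Random(seed)
        names = ["A", "B", "C", "D"]
        tracks = [_track(n, Feature.DISORDER,
                         "".join(rng.choice("*.") for _ in range(12)))
                  for n in names]
        result = consensus_binary(tracks, Feature.DISORDER)
        for i, call in enumerate(result.symbols):
            votes = sum(t.symbols[i] == "*" for t in tracks)
            assert (call == "*") == (votes >= 2)


class TestSpTmConflict:
    def _sp(self, symbols):
        return ConsensusTrack(Feature.SIGNAL, symbols)

    def _tm(self, symbols):
        return ConsensusTrack(Feature.TM, symbols)

    def test_overlapping_tm_run_is_cleared(self):
        sp = self._sp("S" * 22 + "." * 78)
        tm = self._tm("." * 4 + "H" * 21 + "." * 75)  # helix 5-25
        _, tm2 = resolve_sp_tm(sp, tm)
        assert tm2.symbols == "." * 100

    def test_distant_tm_run_is_kept(self):
        sp = self._sp("S" * 22 + "." * 78)
        tm = self._tm("." * 39 + "H" * 21 + "." * 40)  # helix 40-60
        _, tm2 = resolve_sp_tm(sp, tm)
        assert tm2.symbols == tm.symbols

    def test_no_signal_peptide_leaves_tm_unchanged(self):
        sp = self._sp("." * 100)
        tm = self._tm("H" * 20 + "." * 80)
        _, tm2 = resolve_sp_tm(sp, tm)
        assert tm2.symbols == tm.symbols

    def test_internal_signal_run_does_not_count(self):
        # a positive run not anchored at residue 1 is not a signal peptide
        sp = self._sp("." * 10 + "S" * 12 + "." * 78)
        tm = self._tm("H" * 15 + "." * 85)
        _, tm2 = resolve_sp_tm(sp, tm)
        assert tm2.symbols == tm.symbols

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValidationError):
            resolve_sp_tm(self._sp("S" * 10), self._tm("." * 12))


class TestProfileFilter:
    @pytest.mark.parametrize("cov,identity,kept", [
        (50.0, 80.0, True),
        (40.0, 80.0, False),   # coverage must exceed 40, strictly
        (95.0, 95.0, False),   # too similar for the profile
        (41.0, 90.0, False),   # identity must be under 90, strictly
        (41.0, 89.9, True),
    ])
    def test_filter_boundaries(self, cov, identity, kept):
        hits = profile_filter([_hit(cov, identity)])
        assert bool(hits) == kept


class TestConservation:
    def _query(self, residues):
        return QuerySequence("q", residues)

    def test_identical_column_scores_nine(self):
        q = self._query("A" * 30)
        track = conservation_track(q, {"h1": "A" * 30, "h2": "A" * 30})
        assert track.symbols == "9" * 30

    def test_uniform_column_scores_zero(self):
        q = self._query("ACDEFGHIKLMNPQRSTVWY" + "A" * 10)
        aligned = {}
        residues = "ACDEFGHIKLMNPQRSTVWY"
        for k in range(19):  # with the query: each residue exactly once
            shifted = residues[k + 1:] + residues[:k + 1]
            aligned[f"h{k}"] = shifted + "-" * 10
        track = conservation_track(q, aligned)
        assert set(track.symbols[:20]) == {"0"}

    def test_three_quarter_majority_column(self):
        # column {A, A, A, G}: H = -(3/4 ln 3/4 + 1/4 ln 1/4) ~ 0.5623,
        # index = 1 - H/ln20 ~ 0.812 -> digit 8
        q = self._query("A" * 30)
        aligned = {"h1": "A" * 30, "h2": "A" * 30, "h3": "G" * 30}
        track = conservation_track(q, aligned)
        assert track.symbols == "8" * 30

    def test_no_hits_defaults_to_query_only(self):
        q = self._query("A" * 30)
        assert conservation_track(q, {}).symbols == "9" * 30

    @given(st.integers(0, 2 ** 30))
    def test_values_in_range_and_gap_handling(self, seed):
        rng = random.Random(seed)
        q = self._query("".join(rng.choice("ACDEFG") for _ in range(40)))
        aligned = {f"h{j}": "".join(rng.choice("ACDEFG-") for _ in range(40))
                   for j in range(3)}
        track = conservation_track(q, aligned)
        assert set(track.symbols) <= set("0123456789")
        # binning is monotone: recompute the value per column
        for i, digit in enumerate(track.symbols):
            col = [q.residues[i]] + [aligned[h][i] for h in aligned]
            counts = Counter(c for c in col if c != "-")
            n = sum(counts.values())
            h = -sum(v / n * math.log(v / n) for v in counts.values())
            value = 1 - h / math.log(20)
            assert int(digit) == min(int(value * 10), 9)
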