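"""Per-residue consensus over predictor tracks.

Each local feature (secondary structure, disorder, transmembrane helices,
signal peptides, ...) is predicted by several independent programs whose
outputs are aligned to the query as one-symbol-per-residue strings.  The
final call at each position is decided by weighted voting: most predictors
carry one vote, while predictors with documented higher accuracy (PSIPRED
for secondary structure, Phobius for signal peptides) carry two.

Binary features are called positive when the weighted positive votes reach
a per-feature threshold; three-state secondary structure takes the
plurality state, with ties resolved in favour of the double-weighted
predictor and otherwise to coil.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .iofmt import (
    FEATURE_ALPHABET,
    POSITIVE_SYMBOL,
    Feature,
    HitRecord,
    PredictionTrack,
    QuerySequence,
    ValidationError,
)

#: natural-log entropy ceiling for a 20-letter residue alphabet
_LN20 = math.log(20.0)

DEFAULT_WEIGHTS = {"PSIPRED": 2, "Phobius": 2}

#: minimum weighted positive votes for a positive consensus call
DEFAULT_MIN_VOTES = {
    Feature.DISORDER: 2,  # positive when called by at least two predictors
    Feature.SIGNAL: 3,    # 3 of 5 votes (Phobius carries 2)
    Feature.COIL: 1,
    Feature.LOWCOMPLEX: 1,
}


@dataclass(frozen=True)
class VoteConfig:
    """Vote weights per predictor and positive-call thresholds per feature.

    Features absent from ``min_votes`` (transmembrane helices by default)
    require a strict majority of the votes actually contributed.
    """

    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    min_votes: dict = field(default_factory=lambda: dict(DEFAULT_MIN_VOTES))

    def weight(self, predictor: str) -> int:
        return self.weights.get(predictor, 1)


@dataclass(frozen=True)
class ConsensusTrack:
    """Final per-residue calls for one feature, with the vote tallies."""

    feature: Feature
    symbols: str
    tallies: tuple = ()  # one Counter-like dict per residue

    def to_prediction_track(self) -> PredictionTrack:
        return PredictionTrack("CONSENSUS", self.feature, self.symbols)


def consensus_ss3(tracks: list[PredictionTrack],
                  config: VoteConfig | None = None) -> ConsensusTrack:
    """Vote H/E/C at every residue over the secondary-structure tracks.

    A coil-only predictor (symbols 'C' where it calls coil, '.' elsewhere)
    contributes a C vote only at its coil positions.  Ties go to the state
    called by the heaviest-weighted predictor present at that residue, and
    failing that to C.
    """
    config = config or VoteConfig()
    ss3 = [t for t in tracks if t.feature == Feature.SS3]
    if not ss3:
        raise ValidationError("no secondary-structure tracks supplied")
    length = len(ss3[0].symbols)
    symbols = []
    tallies = []
    # heaviest predictor first so the tie-break scan is deterministic
    by_weight = sorted(ss3, key=lambda t: (-config.weight(t.predictor), t.predictor))
    for i in range(length):
        tally: Counter = Counter()
        for t in ss3:
            s = t.symbols[i]
            if s != ".":
                tally[s] += config.weight(t.predictor)
        if not tally:
            symbols.append("C")
            tallies.append({})
            continue
        best = max(tally.values())
        leaders = {s for s, v in tally.items() if v == best}
        if len(leaders) == 1:
            call = leaders.pop()
        else:
            # tie: the double-weighted predictor's state wins if it is a
            # leader; otherwise fall back to coil, then lexicographic
            heavy = next((t for t in by_weight
                          if config.weight(t.predictor) > 1
                          and t.symbols[i] in leaders), None)
            if heavy is not None:
                call = heavy.symbols[i]
            elif "C" in leaders:
                call = "C"
            else:
                call = sorted(leaders)[0]
        symbols.append(call)
        tallies.append(dict(tally))
    return ConsensusTrack(Feature.SS3, "".join(symbols), tuple(tallies))


def consensus_binary(tracks: list[PredictionTrack], feature: Feature,
                     config: VoteConfig | None = None) -> ConsensusTrack:
    """Threshold the weighted positive votes for one binary feature.

    The default thresholds are: disorder positive at >= 2 votes, signal
    peptide at >= 3 of the 5 available votes, and transmembrane (or any
    feature without an explicit threshold) at a strict majority of the
    votes contributed by the predictors actually present.
    """
    config = config or VoteConfig()
    tracks = [t for t in tracks if t.feature == feature]
    if not tracks:
        raise ValidationError(f"no {feature.value} tracks supplied")
    positive = POSITIVE_SYMBOL[feature]
    total_votes = sum(config.weight(t.predictor) for t in tracks)
    threshold = config.min_votes.get(feature)
    if threshold is None:
        threshold = total_votes // 2 + 1  # strict majority
    length = len(tracks[0].symbols)
    symbols = []
    tallies = []
    for i in range(length):
        votes = sum(config.weight(t.predictor)
                    for t in tracks if t.symbols[i] == positive)
        symbols.append(positive if votes >= threshold else ".")
        tallies.append({positive: votes, ".": total_votes - votes})
    return ConsensusTrack(feature, "".join(symbols), tuple(tallies))


def _runs(symbols: str, positive: str) -> list[tuple[int, int]]:
    """1-based inclusive intervals of consecutive positive calls."""
    runs = []
    start = None
    for i, s in enumerate(symbols, start=1):
        if s == positive and start is None:
            start = i
        elif s != positive and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(symbols)))
    return runs


def resolve_sp_tm(sp: ConsensusTrack,
                  tm: ConsensusTrack) -> tuple[ConsensusTrack, ConsensusTrack]:
    """Remove transmembrane calls that conflict with an N-terminal signal peptide.

    A consensus signal peptide is a positive run starting at residue 1.
    N-terminal hydrophobic stretches are frequently mistaken for membrane
    helices, so any TM run overlapping the signal-peptide run is cleared;
    without a consensus signal peptide both tracks pass through unchanged.
    """
    if len(sp.symbols) != len(tm.symbols):
        raise ValidationError("signal and TM tracks differ in length")
    sp_runs = _runs(sp.symbols, POSITIVE_SYMBOL[Feature.SIGNAL])
    if not sp_runs or sp_runs[0][0] != 1:
        return sp, tm
    sp_end = sp_runs[0][1]
    tm_pos = POSITIVE_SYMBOL[Feature.TM]
    cleared = list(tm.symbols)
    for start, end in _runs(tm.symbols, tm_pos):
        if start <= sp_end:  # overlaps the N-terminal signal run
            for i in range(start - 1, end):
                cleared[i] = "."
    return sp, ConsensusTrack(tm.feature, "".join(cleared), tm.tallies)


def profile_filter(hits: list[HitRecord]) -> list[HitRecord]:
    """Keep hits suitable for a conservation profile.

    Hits must span more than 40% of the query (informative alignment) and
    be under 90% identical (to avoid redundancy dominating the profile).
    Both inequalities are strict.
    """
    return [h for h in hits if h.q_cov_pct > 40.0 and h.identity_pct < 90.0]


def conservation_track(query: QuerySequence,
                       aligned_hits: dict[str, str]) -> ConsensusTrack:
    """Per-residue conservation index from profile-filtered homologs.

    At each query position the index is 1 - H/ln(20), where H is the
    Shannon entropy of the residue distribution observed in that column
    (query residue included, gaps ignored).  The index is binned to a
    digit 0-9 as floor(10 * index), with 1.0 mapping to 9.  With no hits
    every column is a single residue, hence index 1 and digit 9.
    """
    digits = []
    rows = list(aligned_hits.values())
    for i in range(query.length):
        column = [query.residues[i]] + [r[i] for r in rows]
        counts = Counter(c for c in column if c != "-")
        n = sum(counts.values())
        entropy = -sum((v / n) * math.log(v / n) for v in counts.values())
        value = 1.0 - entropy / _LN20
        digits.append(str(min(int(value * 10.0), 9)))
    return ConsensusTrack(Feature.CONSERVATION, "".join(digits))


def consensus_all(tracks: list[PredictionTrack],
                  config: VoteConfig | None = None) -> list[ConsensusTrack]:
    """Run every applicable consensus over a bundle's track set.

    Secondary structure is voted three-state; disorder, TM, signal, coiled
    coil and low complexity are voted binary; the signal/TM conflict rule
    is then applied.  Features with no tracks are skipped.
    """
    config = config or VoteConfig()
    out: dict[Feature, ConsensusTrack] = {}
    if any(t.feature == Feature.SS3 for t in tracks):
        out[Feature.SS3] = consensus_ss3(tracks, config)
    for feature in (Feature.DISORDER, Feature.TM, Feature.SIGNAL,
                    Feature.COIL, Feature.LOWCOMPLEX):
        if any(t.feature == feature for t in tracks):
            out[feature] = consensus_binary(tracks, feature, config)
    if Feature.SIGNAL in out and Feature.TM in out:
        out[Feature.SIGNAL], out[Feature.TM] = resolve_sp_tm(
            out[Feature.SIGNAL], out[Feature.TM])
    order = [Feature.SS3, Feature.DISORDER, Feature.TM, Feature.SIGNAL,
             Feature.COIL, Feature.LOWCOMPLEX]
    return [out[f] for f in order if f in out]
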