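"""Deterministic synthetic prediction bundles for testing and demos.

No external predictor or database is ever executed: this module plants a
known ground truth (secondary-structure string, signal-peptide /
transmembrane / disorder segments, GO terms, an EC number, a template
layout) and emits the files a real prediction run would produce —
predictor tracks equal to the truth corrupted by independent per-residue
symbol flips, and hit tables whose statistics decay smoothly down the
ranking.  The same seed always yields a byte-identical bundle.

The noise model is deliberately simple (independent symbol flips at a
single per-predictor rate, 10% by default): it exercises the voting
machinery without emulating any real predictor's error profile.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .iofmt import (
    Bundle,
    Collection,
    FEATURE_ALPHABET,
    Feature,
    HitRecord,
    Method,
    POSITIVE_SYMBOL,
    PredictionTrack,
    QuerySequence,
    ValidationError,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: default predictor roster per feature (vote weights live in VoteConfig)
SS3_PREDICTORS = ("PSIPRED", "SSPRO")
DISORDER_PREDICTORS = ("DISEMBL-missing", "DISPRO", "DISOPRED", "IsUnstruct")
SIGNAL_PREDICTORS = ("SignalP-HMM", "SignalP-NN", "MEMSATSVM", "Phobius")
TM_PREDICTORS = ("TMHMM", "TOPPRED", "HMMTOP", "MEMSAT", "MEMSATSVM", "Phobius")


@dataclass(frozen=True)
class PlantedTruth:
    """The ground truth a synthetic bundle was generated from."""

    ss3: str
    signal: str
    tm: str
    disorder: str
    go_terms: tuple
    ec: str
    template_layout: tuple  # (template_id, q_start, q_end) by rank


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic bundle.

    Defaults describe a typical well-annotated bacterial protein: a
    240-residue secreted enzyme with an N-terminal signal peptide, a
    disordered C-terminal tail, close Swiss-Prot homologs and a template
    layout covering most of the chain.  ``noise_rate`` is the independent
    per-residue probability that a predictor reports a wrong symbol.
    """

    seed: int
    length: int = 240
    n_sprot_hits: int = 8
    n_go_hits: int = 6
    n_templates: int = 4
    noise_rate: float = 0.1
    with_signal: bool = True
    ss3_predictors: tuple = SS3_PREDICTORS
    template_layout: Optional[tuple] = None  # override (id, start, end) triples

    def __post_init__(self) -> None:
        if not (30 <= self.length <= 4000):
            raise ValidationError(
                f"fixture length {self.length} outside the 30-4000 query range")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValidationError("noise_rate must be in [0, 1)")


def _plant_truth(spec: FixtureSpec, rng: random.Random) -> PlantedTruth:
    L = spec.length
    sp_len = 22 if (spec.with_signal and L >= 60) else 0
    signal = "S" * sp_len + "." * (L - sp_len)

    # secondary structure: coil over the signal peptide, then alternating
    # helix/strand segments separated by short coils
    ss3 = ["C"] * L
    i = sp_len + 2
    state = "H"
    while i < L:
        seg = rng.randint(8, 18) if state == "H" else rng.randint(5, 10)
        for j in range(i, min(i + seg, L)):
            ss3[j] = state
        i += seg + rng.randint(3, 6)
        state = "E" if state == "H" else "H"

    # disordered C-terminal tail (~12% of the chain) plus coil there
    tail = max(10, L // 8) if L >= 80 else 0
    disorder = "." * (L - tail) + "*" * tail
    for j in range(L - tail, L):
        ss3[j] = "C"
    truth_ss3 = "".join(ss3)

    if spec.template_layout is not None:
        layout = tuple(spec.template_layout)
    else:
        layout = []
        usable = L - tail
        span = max(usable * 2 // 3, min(usable, 30))
        start = 1
        for k in range(spec.n_templates):
            end = min(start + span - 1, usable)
            layout.append((f"T{k:02d}", max(1, start), max(end, 1)))
            start += max(span // 2, 1)
            if start >= usable:
                start = 1 + k  # lower-ranked redundant templates
        layout = tuple(layout)

    return PlantedTruth(
        ss3=truth_ss3,
        signal=signal,
        tm="." * L,
        disorder=disorder,
        go_terms=("GO:0016491", "GO:0055114"),
        ec="1.1.1.1",
        template_layout=layout,
    )


def _noisy(truth: str, feature: Feature, rate: float,
           rng: random.Random) -> str:
    """Corrupt a truth string with independent per-residue symbol flips."""
    alphabet = sorted(FEATURE_ALPHABET[feature] - {"."}) \
        if feature == Feature.SS3 else None
    out = []
    positive = POSITIVE_SYMBOL.get(feature)
    for s in truth:
        if rng.random() >= rate:
            out.append(s)
        elif feature == Feature.SS3:
            out.append(rng.choice([c for c in alphabet if c != s]))
        else:
            out.append("." if s == positive else positive)
    return "".join(out)


def _coil_only(ss3_truth: str, rate: float, rng: random.Random) -> str:
    flipped = _noisy(ss3_truth, Feature.SS3, rate, rng)
    return "".join("C" if s == "C" else "." for s in flipped)


def _make_tracks(truth: PlantedTruth, spec: FixtureSpec,
                 rng: random.Random) -> list[PredictionTrack]:
    tracks = []
    for name in spec.ss3_predictors:
        tracks.append(PredictionTrack(
            name, Feature.SS3, _noisy(truth.ss3, Feature.SS3,
                                      spec.noise_rate, rng)))
    tracks.append(PredictionTrack(
        "DISEMBL-coils", Feature.SS3,
        _coil_only(truth.ss3, spec.noise_rate, rng)))
    for name in DISORDER_PREDICTORS:
        tracks.append(PredictionTrack(
            name, Feature.DISORDER,
            _noisy(truth.disorder, Feature.DISORDER, spec.noise_rate, rng)))
    for name in SIGNAL_PREDICTORS:
        tracks.append(PredictionTrack(
            name, Feature.SIGNAL,
            _noisy(truth.signal, Feature.SIGNAL, spec.noise_rate, rng)))
    for name in TM_PREDICTORS:
        tracks.append(PredictionTrack(
            name, Feature.TM,
            _noisy(truth.tm, Feature.TM, spec.noise_rate, rng)))
    tracks.append(PredictionTrack("COILS", Feature.COIL, "." * spec.length))
    tracks.append(PredictionTrack("SEG", Feature.LOWCOMPLEX, "." * spec.length))
    return tracks


def _sprot_hits(truth: PlantedTruth, spec: FixtureSpec,
                rng: random.Random) -> list[HitRecord]:
    L = spec.length
    hits = []
    evidence = ["IDA", "TAS", "ISS", "IEA"]
    for i in range(spec.n_sprot_hits):
        identity = max(25.0, 95.0 - 8.0 * i - rng.random() * 3.0)
        cov = max(35.0, 92.0 - 4.0 * i - rng.random() * 3.0)
        exponent = max(2, 80 - 9 * i)
        go = ()
        if i < 4:
            go = tuple((t, evidence[min(i, len(evidence) - 1)])
                       for t in truth.go_terms[:1 + (i % 2)])
        ec = (truth.ec,) if i < 3 else ()
        span = max(int(L * cov / 100.0), 1)
        q_start = 1 + rng.randint(0, max(L - span, 0))
        hits.append(HitRecord(
            subject_id=f"SP{i:03d}",
            collection=Collection.SPROT,
            method=Method.BLAST,
            evalue=float(f"1e-{exponent}"),
            identity_pct=round(identity, 1),
            q_start=q_start, q_end=q_start + span - 1,
            s_start=1, s_end=span,
            q_cov_pct=round(cov, 1), s_cov_pct=round(max(cov - 2.0, 30.0), 1),
            annotation=f"synthetic homolog {i} of planted enzyme",
            go_terms=go,
            ec_numbers=ec,
        ))
    return hits


def _go_hits(truth: PlantedTruth, spec: FixtureSpec,
             rng: random.Random) -> list[HitRecord]:
    L = spec.length
    hits = []
    codes = ["IDA", "ISS", "IEA", "IEP", "TAS", "IEA"]
    for i in range(spec.n_go_hits):
        identity = max(28.0, 90.0 - 9.0 * i)
        cov = max(40.0, 88.0 - 5.0 * i)
        term = truth.go_terms[i % len(truth.go_terms)]
        span = max(int(L * cov / 100.0), 1)
        hits.append(HitRecord(
            subject_id=f"GOH{i:03d}",
            collection=Collection.GO,
            method=Method.BLAST,
            evalue=float(f"1e-{max(2, 60 - 10 * i)}"),
            identity_pct=round(identity, 1),
            q_start=1, q_end=span, s_start=1, s_end=span,
            q_cov_pct=round(cov, 1), s_cov_pct=round(cov, 1),
            annotation=f"synthetic GO-annotated hit {i}",
            go_terms=((term, codes[i % len(codes)]),),
        ))
    return hits


#: small ontology fragment rooted at the two planted terms
GO_EDGES = {
    ("GO:0016491", "GO:0003824"),
    ("GO:0003824", "GO:0003674"),
    ("GO:0055114", "GO:0008152"),
    ("GO:0008152", "GO:0008150"),
}


def _template_hits(truth: PlantedTruth, spec: FixtureSpec,
                   rng: random.Random) -> list[HitRecord]:
    hits = []
    L = spec.length
    for rank, (tid, start, end) in enumerate(truth.template_layout):
        start, end = max(1, start), min(end, L)
        if start > end:
            continue
        identity = max(22.0, 60.0 - 12.0 * rank)
        exponent = max(3, 40 - 8 * rank)
        span = end - start + 1
        hits.append(HitRecord(
            subject_id=tid, collection=Collection.PDB, method=Method.BLAST,
            evalue=float(f"1e-{exponent}"), identity_pct=identity,
            q_start=start, q_end=end, s_start=1, s_end=span,
            q_cov_pct=round(100.0 * span / L, 1), s_cov_pct=95.0,
            annotation=f"synthetic structure template rank {rank}"))
        if rank == 0:  # the top template is also found by profile search
            hits.append(HitRecord(
                subject_id=tid, collection=Collection.PDB, method=Method.HHPRED,
                probability_pct=min(100.0, 99.9 - 3.0 * rank),
                identity_pct=identity,
                q_start=start, q_end=end, s_start=1, s_end=span,
                q_cov_pct=round(100.0 * span / L, 1), s_cov_pct=95.0,
                annotation=f"synthetic structure template rank {rank}"))
    return hits


def make_bundle(spec: FixtureSpec) -> tuple[Bundle, PlantedTruth]:
    """Generate one coherent bundle plus the truth it was planted from."""
    rng = random.Random(spec.seed)
    truth = _plant_truth(spec, rng)
    residues = "".join(rng.choice(_AA) for _ in range(spec.length))
    query = QuerySequence(id=f"synthetic-{spec.seed}", residues=residues)

    bundle = Bundle(query=query)
    bundle.tracks = _make_tracks(truth, spec, rng)
    bundle.sprot_hits = _sprot_hits(truth, spec, rng)
    bundle.go_hits = _go_hits(truth, spec, rng)
    bundle.template_hits = _template_hits(truth, spec, rng)
    bundle.go_edges = set(GO_EDGES)
    scores_by_hit = {}
    bundle.ec_evidence = []
    for hit in bundle.sprot_hits:
        for ec in hit.ec_numbers:
            bundle.ec_evidence.append({"source": "TRANSFER", "ec": ec,
                                       "confidence": None,
                                       "subject_id": hit.subject_id})
    bundle.ec_evidence.append({"source": "EZYPRED",
                               "ec": truth.ec.rsplit(".", 2)[0] + ".-.-",
                               "confidence": None, "subject_id": ""})
    bundle.ec_evidence.append({"source": "EFICAZ", "ec": truth.ec,
                               "confidence": 0.9, "subject_id": ""})
    # reciprocal tables: the closest homolog is a true ortholog
    if bundle.sprot_hits:
        import dataclasses
        bundle.proteome_fwd = [
            dataclasses.replace(h, collection=Collection.NR,
                                go_terms=(), ec_numbers=())
            for h in bundle.sprot_hits]
        best = bundle.sprot_hits[0]
        rev_hit = HitRecord(
            subject_id=query.id, collection=Collection.NR, method=Method.BLAST,
            evalue=best.evalue, identity_pct=best.identity_pct,
            q_start=best.s_start, q_end=best.s_end,
            s_start=best.q_start, s_end=best.q_end,
            q_cov_pct=best.s_cov_pct, s_cov_pct=best.q_cov_pct,
            annotation="reciprocal search of the best homolog")
        bundle.proteome_rev = {best.subject_id: [rev_hit]}
    return bundle, truth


# ---------------------------------------------------------------------------
# the canonical worked example (hand-computed expected report)


WORKED_SEQ = (
    "MKKLLLVLLACLLPSSWAQA"
    "SDTGRRAFVEMVEEGKLPAE"
    "LVKELVRSGDRVVITGAGGS"
    "IGSELCRQLAKLGAKVIALD"
    "RSEEALQELKEELGDNVIFI"
    "EGDVTSYEDNKRAVDAAVSK"
)

WORKED_SS3 = "C" * 24 + "H" * 26 + "C" * 10 + "E" * 20 + "C" * 10 + "H" * 20 + "C" * 10
WORKED_SIGNAL = "S" * 20 + "." * 100
WORKED_TM_RAW = "." * 4 + "H" * 21 + "." * 95  # false TM over the signal peptide
WORKED_DISORDER = "." * 100 + "*" * 20


def worked_example() -> tuple[Bundle, "object"]:
    """A hand-built 120-residue bundle and its expected report.

    Every expected score below was summed by hand from the rubrics; the
    bundle doubles as the canonical regression fixture.  Noteworthy
    plants: a false transmembrane helix overlapping the signal peptide
    (cleared by the conflict rule), a GO term reaching the full 12 points
    via the three-hit consensus bonus, and a third template fully covered
    by the first two (rejected by the 30-new-residue rule).
    """
    from . import ec_annotation, go_annotation, homology, structure_templates
    from .feature_consensus import ConsensusTrack
    from .iofmt import Report

    query = QuerySequence(id="demo", residues=WORKED_SEQ)
    bundle = Bundle(query=query)

    bundle.tracks = [
        PredictionTrack("PSIPRED", Feature.SS3, WORKED_SS3),
        PredictionTrack("SSPRO", Feature.SS3, WORKED_SS3),
        PredictionTrack("DISEMBL-coils", Feature.SS3,
                        "".join("C" if s == "C" else "." for s in WORKED_SS3)),
        *[PredictionTrack(p, Feature.DISORDER, WORKED_DISORDER)
          for p in DISORDER_PREDICTORS],
        *[PredictionTrack(p, Feature.SIGNAL, WORKED_SIGNAL)
          for p in SIGNAL_PREDICTORS],
        *[PredictionTrack(p, Feature.TM, WORKED_TM_RAW)
          for p in ("TMHMM", "HMMTOP", "MEMSAT", "Phobius")],
        PredictionTrack("COILS", Feature.COIL, "." * 120),
        PredictionTrack("SEG", Feature.LOWCOMPLEX, "." * 120),
    ]

    def sprot(sid, evalue, ident, qcov, scov, go=(), ec=()):
        return HitRecord(
            subject_id=sid, collection=Collection.SPROT, method=Method.BLAST,
            evalue=evalue, identity_pct=ident, q_start=1,
            q_end=int(120 * qcov / 100), s_start=1, s_end=int(120 * scov / 100),
            q_cov_pct=qcov, s_cov_pct=scov,
            annotation=f"synthetic Swiss-Prot homolog {sid}",
            go_terms=go, ec_numbers=ec)

    bundle.sprot_hits = [
        sprot("SPH001", 1e-80, 95.0, 90.0, 90.0,
              go=(("GO:0016491", "IDA"),), ec=("1.1.1.1",)),
        sprot("SPH002", 1e-30, 65.0, 75.0, 70.0,
              go=(("GO:0016491", "IEA"),), ec=("1.1.1.1",)),
        sprot("SPH003", 1e-10, 40.0, 50.0, 45.0, ec=("1.1.1.1",)),
    ]
    import dataclasses as _dc
    bundle.proteome_fwd = [
        _dc.replace(h, collection=Collection.NR, go_terms=(), ec_numbers=())
        for h in bundle.sprot_hits]
    bundle.proteome_rev = {"SPH001": [HitRecord(
        subject_id="demo", collection=Collection.NR, method=Method.BLAST,
        evalue=1e-80, identity_pct=95.0, q_start=1, q_end=108,
        s_start=1, s_end=108, q_cov_pct=90.0, s_cov_pct=90.0,
        annotation="reciprocal search")]}

    def gohit(sid, evalue, ident, qcov, scov, terms):
        return HitRecord(
            subject_id=sid, collection=Collection.GO, method=Method.BLAST,
            evalue=evalue, identity_pct=ident, q_start=1,
            q_end=int(120 * qcov / 100), s_start=1, s_end=int(120 * scov / 100),
            q_cov_pct=qcov, s_cov_pct=scov,
            annotation=f"synthetic GO hit {sid}", go_terms=terms)

    bundle.go_hits = [
        gohit("GOH1", 1e-60, 90.0, 85.0, 85.0, (("GO:0016491", "IDA"),)),
        gohit("GOH2", 1e-40, 72.0, 80.0, 82.0, (("GO:0016491", "ISS"),)),
        gohit("GOH3", 1e-20, 55.0, 65.0, 70.0,
              (("GO:0016491", "IEA"), ("GO:0055114", "IEP"))),
        gohit("GOH4", 1e-5, 35.0, 50.0, 55.0, (("GO:0055114", "IEA"),)),
    ]
    bundle.go_edges = set(GO_EDGES)

    bundle.ec_evidence = [
        {"source": "TRANSFER", "ec": "1.1.1.1", "confidence": None,
         "subject_id": "SPH001"},
        {"source": "TRANSFER", "ec": "1.1.1.1", "confidence": None,
         "subject_id": "SPH002"},
        {"source": "TRANSFER", "ec": "1.1.1.1", "confidence": None,
         "subject_id": "SPH003"},
        {"source": "EZYPRED", "ec": "1.1.-.-", "confidence": None,
         "subject_id": ""},
        {"source": "EFICAZ", "ec": "1.1.1.1", "confidence": 0.85,
         "subject_id": ""},
    ]

    def template(tid, method, q_start, q_end, ident, evalue=None, prob=None):
        span = q_end - q_start + 1
        return HitRecord(
            subject_id=tid, collection=Collection.PDB, method=method,
            evalue=evalue, probability_pct=prob, identity_pct=ident,
            q_start=q_start, q_end=q_end, s_start=1, s_end=span,
            q_cov_pct=round(100.0 * span / 120, 1), s_cov_pct=95.0,
            annotation=f"synthetic template {tid}")

    bundle.template_hits = [
        template("1abcA", Method.BLAST, 5, 80, 45.0, evalue=1e-60),
        template("1abcA", Method.HHPRED, 5, 80, 45.0, prob=99.9),
        template("2xyzB", Method.HHPRED, 71, 120, 30.0, prob=92.0),
        template("3pqrC", Method.BLAST, 80, 120, 25.0, evalue=1e-8),
    ]

    # ------------------------------------------------------------------
    # expected report, every number summed by hand from the rubrics

    Tier = homology.Tier
    consensus_tracks = [
        PredictionTrack("CONSENSUS", Feature.SS3, WORKED_SS3),
        PredictionTrack("CONSENSUS", Feature.DISORDER, WORKED_DISORDER),
        PredictionTrack("CONSENSUS", Feature.TM, "." * 120),  # cleared by SP
        PredictionTrack("CONSENSUS", Feature.SIGNAL, WORKED_SIGNAL),
        PredictionTrack("CONSENSUS", Feature.COIL, "." * 120),
        PredictionTrack("CONSENSUS", Feature.LOWCOMPLEX, "." * 120),
    ]

    homologs = [
        # 1 (e) + 4 (id 95) + 2 (cov 90/90) + 2 (fwd best) + 2 (rev best) = 11
        homology.RankedHomolog(
            "SPH001", "synthetic Swiss-Prot homolog SPH001", 1e-80, 95.0,
            homology.HomologScore(1, 4, 2, 2, 2, 11, Tier.VERY_CONFIDENT),
            ec_numbers=("1.1.1.1",), go_terms=(("GO:0016491", "IDA"),)),
        # 1 + 2 (id 65) + 1 (cov 75/70) + 0 + 1 (rev n/a) = 5
        homology.RankedHomolog(
            "SPH002", "synthetic Swiss-Prot homolog SPH002", 1e-30, 65.0,
            homology.HomologScore(1, 2, 1, 0, 1, 5, Tier.UNASSIGNED),
            ec_numbers=("1.1.1.1",), go_terms=(("GO:0016491", "IEA"),)),
        # 1 + 1 (id 40) + 0 (cov 50/45) + 0 + 1 = 3
        homology.RankedHomolog(
            "SPH003", "synthetic Swiss-Prot homolog SPH003", 1e-10, 40.0,
            homology.HomologScore(1, 1, 0, 0, 1, 3, Tier.UNASSIGNED),
            ec_numbers=("1.1.1.1",)),
    ]

    # GO:0016491 best hit GOH1: 1+4+2+3 = 10; three distinct hits -> +2 = 12
    go_oxido = go_annotation.GoTermScore(
        "GO:0016491", 1, 4, 2, 3, 2, 12, Tier.VERY_CONFIDENT,
        supporting_hits=("GOH1", "GOH2", "GOH3"))
    # GO:0055114 best hit GOH3: 1+2+1+2 = 6; only two hits -> no bonus
    go_oxproc = go_annotation.GoTermScore(
        "GO:0055114", 1, 2, 1, 2, 0, 6, Tier.PROBABLE,
        supporting_hits=("GOH3", "GOH4"))

    def inherit(term, src, base):
        return go_annotation.GoTermScore(
            term, base.points_evalue, base.points_identity,
            base.points_coverage, base.points_evidence, base.points_consensus,
            base.total, base.tier, supporting_hits=base.supporting_hits,
            propagated_from=src)

    go_terms = [
        inherit("GO:0003674", "GO:0016491", go_oxido),
        inherit("GO:0003824", "GO:0016491", go_oxido),
        go_oxido,
        inherit("GO:0008150", "GO:0055114", go_oxproc),
        inherit("GO:0008152", "GO:0055114", go_oxproc),
        go_oxproc,
    ]

    # 1.1.1.1: transfer 3 (SPH001 total 11 >= 10) + consensus 1 (three hits)
    # + Ezypred agree 2 + EFICAz 0.85 -> 3.5; total 9.5
    ec_numbers = [ec_annotation.EcPrediction(
        ec_annotation.EcNumber.parse("1.1.1.1"), 3.0, 1.0, 2.0, 3.5, 9.5,
        Tier.VERY_CONFIDENT,
        sources=frozenset({"TRANSFER", "EZYPRED", "EFICAZ"}))]

    # 1abcA: identity 45 -> 2, prob 99.9 -> 4, e 1e-60 -> 4, two methods -> 1
    t1 = structure_templates.TemplateScore(
        "1abcA", frozenset({Method.BLAST, Method.HHPRED}), 2, 4, 4, 1, 11,
        ((5, 80),), best_evalue=1e-60, best_probability=99.9,
        tier=Tier.VERY_CONFIDENT)
    # 2xyzB: identity 30 -> 1, prob 92 -> 3; total 4
    t2 = structure_templates.TemplateScore(
        "2xyzB", frozenset({Method.HHPRED}), 1, 3, 0, 0, 4,
        ((71, 120),), best_evalue=None, best_probability=92.0,
        tier=Tier.CONFIDENT)
    # 3pqrC scores 1 + 2 = 3 but adds no new residues -> rejected in selection

    expected = Report(
        query=query,
        consensus_tracks=consensus_tracks,
        homologs=homologs,
        go_terms=go_terms,
        ec_numbers=ec_numbers,
        is_enzyme=True,
        templates=[t1, t2],
        # selection covers 5-120 = 116 of 120 residues; the disordered tail
        # is inside the covered region, so the combined fraction is equal
        coverage_summary={
            "covered_fraction": 116 / 120,
            "covered_or_disordered_fraction": 116 / 120,
            "high_coverage": True,
        },
        metadata={"organism_type": "UNKNOWN"},
    )
    return bundle, expected
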