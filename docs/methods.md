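# Methods

This note documents the models and conventions behind `metannot`: how
consensus calls, confidence scores and the template set are computed, the
parameters that matter, and what the synthetic bundles do and do not
demonstrate.

## Inputs and coordinates

A prediction bundle holds, for one query protein of 30–4,000 residues,
the query sequence plus normalized TSV files: per-residue predictor
tracks (`tracks.tsv`), homology hit tables in a BLAST-outfmt-6-like
dialect with annotation columns (`hits_<collection>.tsv`), a GO
parent-edge list (`go_edges.tsv`), EC evidence rows (`ec_evidence.tsv`),
optional per-hit alignment strings for the conservation index
(`alignments_nr.tsv`), and optional proteome search tables for
reciprocal-best-hit checks (`proteome_fwd.tsv`, `proteome_rev.tsv` — the
latter carries a leading `searched_id` column grouping one reverse search
per homolog). All coordinates are 1-based inclusive. Native predictor
output formats are version-dependent, so one normalized dialect per input
class is defined instead; converters are out of scope.

Binary tracks use the display letter of the feature for positive calls
(`H` transmembrane, `S` signal peptide, `*` disorder, `x` coiled
coil/low complexity) and `.` for negatives. The three-state secondary
structure alphabet is `H`/`E`/`C` plus `.` as an explicit no-call, which
lets coil-only predictors vote C at their coil positions and abstain
elsewhere within the same file format.

## Consensus voting

At each residue every predictor casts its vote; most carry one vote,
while PSIPRED (secondary structure) and Phobius (signal peptides) carry
two, reflecting their documented accuracy. Defaults live in
`VoteConfig` and can be overridden per run.

- **Secondary structure**: plurality of weighted H/E/C votes. On a tie,
  the double-weighted predictor's state wins if it is among the leaders;
  otherwise C; otherwise (an H/E tie with no heavy voter) the
  lexicographically first leader. The tie ladder is a design choice — the
  voting scheme itself only privileges the double-weighted predictor.
- **Binary features**: positive when weighted positive votes reach the
  feature threshold. Disorder: ≥ 2 votes. Signal peptide: ≥ 3 of the 5
  available votes (SignalP-HMM, SignalP-NN, MEMSAT-SVM one each, Phobius
  two) — chosen so that consensus between predictors is required but
  Phobius plus any one other suffices. Transmembrane (and any feature
  without an explicit threshold): a strict majority of the votes actually
  contributed, which stays meaningful when predictors are missing.
- **Signal/TM conflict**: an N-terminal hydrophobic signal peptide is
  easily mistaken for a membrane helix. When the consensus signal
  peptide exists (a positive run starting at residue 1), every TM run
  overlapping it is cleared; otherwise both tracks pass unchanged.
  Individual TM topologies are passed through unmodified.
- **Conservation**: homologs filtered to query coverage > 40% and
  identity < 90% (both strict) form the profile. Per column the index is
  1 − H/ln 20, with H the Shannon entropy of the observed residues
  (query included, gaps ignored), binned to a digit by ⌊10·index⌋ with
  1.0 → 9. This entropy index is this package's own conservation
  measure; it is monotone and bounded but not identical to
  frequency-weighted indices used elsewhere.

## Confidence rubrics

**Homologs (0–12, tiers 10/8/6).** e-value < 0.001 → 1. Identity
(requiring both coverages > 40%): 30–50/50–70/70–90/90–99/>99% → 1–5.
Mutual coverage: both ≥ 60% → 1, both ≥ 80% → 2. Reciprocal best hit,
each direction: best → 2, table unavailable → 1, not best → 0. The
printed bins share endpoints, so a single convention is used throughout:
bins are closed on the left and open on the right, with the top bin
closed (identity exactly 50 falls in 50–70; exactly 99 in 90–99). The
coverage criterion is evaluated on min(query, hit coverage), the only
reading of "both sides" that keeps the score monotone in each coverage.

**GO terms (0–12, tiers 10/8/6).** Per supporting hit: the same e-value,
identity (top bin 90–100 → 4) and coverage criteria, plus evidence-code
points (EXP, IDA → 3; IPI, IMP, IGI, IEP, ISO, TAS → 2; ISS, ISA, ISM,
IGC, IBA, IBD, IKR, IRD, RCA, NAS, IC, IEA → 1; unknown → 0). The term's
base is the *maximum* over its supporting hits (a max, not a sum, keeps
the 0–12 range valid), +2 when at least three distinct subject ids carry
the term. Scores then propagate upward: every ancestor receives the
maximum of its own direct score and its descendants' scores, recording
the contributing descendant; propagation is idempotent, and on ties a
direct score is kept, else the lexicographically smallest descendant is
recorded. Propagation happens before the reporting cut (total ≥ 6).

**EC numbers (tiers 7/5/3).** Sources predict to different depths, so
two EC numbers *agree* when equal on every level both specify
(1.1.1.1 agrees with 1.1.-.-); candidates that refine one another
collapse to the most specific representative. Transfer points come from
the best agreeing homolog's rubric total: 6–8 → 1, 8–10 → 2, ≥ 10 → 3;
+1 when ≥ 3 distinct Swiss-Prot hits carry an agreeing EC; +2 when the
two-level predictor agrees; four-level predictor confidence: LOW (or a
numeric value below 0.6) → 2, 0.6–0.7 → 2.5, 0.7–0.8 → 3, 0.8–0.9 → 3.5,
0.9–1 → 4. A query is called an enzyme when any prediction reaches the
3-point probable cut. Half points are kept as exact decimals.

**Templates (0–16).** Detection cuts per method: BLAST e ≤ 0.001,
RPS-BLAST e ≤ 0.01, profile-profile probability ≥ 80%. Identity bins
20–40/40–60/60–80/80–90/90–100% → 1–5 on the best hit; probability bins
80–85/85–90/90–99/99–99.99/99.99–100 → 1–5 on the best profile hit;
e-value bins (10⁻⁶,10⁻²] → 1, (10⁻¹⁸,10⁻⁶] → 2, (10⁻⁵⁴,10⁻¹⁸] → 3,
≤ 10⁻⁵⁴ → 4 on the best sequence-search hit (the only disjoint reading
in which points increase with significance); +1/+2 for detection by
two/three methods. Summary tier labels are a display convention:
*very confident* at probability ≥ 99 or e ≤ 10⁻¹⁸, *confident* at
probability ≥ 90 or e ≤ 10⁻⁶, else *probable*.

## Greedy template selection

Templates are ranked by total (ties: e-value ascending, probability
descending, id ascending) and scanned from the top; a template is kept
iff its query range — a union of intervals when a template aligns in
several pieces, with "new residues" counted as a set difference —
contains at least `min_new = 30` residues not covered by previously kept
templates. The same rule applies to the first template: a template under
30 residues is uninformative for modeling. Coverage statistics report
the fraction of residues covered, the fraction covered *or* called
disordered by the consensus (disordered residues are not expected to be
modelable), and a flag for combined coverage above 80%.

## Synthetic bundles

The generator plants a ground truth — a secondary-structure segment
layout, a 22-residue signal peptide, a disordered C-terminal tail
(~12% of the chain), GO terms, an EC number and a template layout — and
derives every bundle file from it. Defaults describe a well-annotated
240-residue bacterial protein: 8 Swiss-Prot hits with smoothly decaying
identity (95% downward) and e-value (10⁻⁸⁰ downward), 6 GO hits, 4
templates, and predictor tracks equal to the truth corrupted by
independent per-residue symbol flips at rate 0.1. The same seed yields a
byte-identical bundle; all randomness flows from one explicitly seeded
generator.

The noise model is deliberately minimal: flips are independent across
residues and predictors, whereas real predictor errors are strongly
correlated (segment boundaries, shared training data, hydrophobicity
confusions). Recovery results on these bundles therefore demonstrate
that the voting, scoring and selection machinery is correct — not that
any particular accuracy would be achieved on real proteins. Recovery is
assessed on features with at least four voters (secondary structure with
four predictors, disorder, signal, TM); single-predictor features (coiled
coil, low complexity) are pass-through by construction. Problem sizes
used in the test suite — queries of 120–300 residues, up to 12 templates,
ontologies of ≤ 30 terms, 300–1,000 randomized instances per property —
were chosen as the smallest sizes that exercise every code path and bin.

The hand-built 120-residue worked example doubles as a regression
fixture: all of its expected scores were summed by hand from the rubrics
and the pipeline must reproduce them field-for-field.

## Degenerate inputs and numerics

Queries outside 30–4,000 residues are rejected up front with the bound
named. Absent optional bundle files skip their section. An empty
profile yields a conservation track of 9s (each column is the query
residue alone). Hits missing an e-value (profile-profile searches)
never earn e-value points and sort after any hit with one. EC confidence
outside [0, 1] (and not LOW) is an error. All scores are small exact
integers or exact halves, so comparisons are exact; no floating-point
tolerances are needed anywhere in the scoring.

## Known limitations

The package scores and integrates predictions; it does not run
predictors, fetch taxonomy or ontology data, build homology models, or
render interactive output. The GO hierarchy is consumed as a plain edge
list (is_a/part_of distinctions collapse). Reciprocal-best-hit checks
assume the caller supplies the two proteome search tables; when absent,
the rubric's N/A point applies. The conservation index treats columns
independently and ignores alignment uncertainty.
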