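"""Reading and writing of prediction bundles and final reports.

A *bundle* is the complete set of inputs for one query protein: the query
sequence (FASTA or plain text), per-residue prediction tracks from named
predictors, tabular homology hits against several collections, a GO
parent-edge table, EC evidence records, and (optionally) per-hit alignment
strings used for the conservation index.  All tabular files are
tab-separated with a header row; coordinates are 1-based inclusive,
matching the BLAST tabular convention.

The module also writes the final report in two forms: a loss-less JSON
document and a human-readable text summary in which every consensus track
is printed as one line aligned under the query sequence.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from Bio import SeqIO


class ValidationError(ValueError):
    """Input is well-formed but violates a documented constraint."""


class ParseError(ValueError):
    """Input file cannot be interpreted in the expected dialect."""


#: the 20 standard amino acids plus X for unknown residues
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

MIN_QUERY_LENGTH = 30
MAX_QUERY_LENGTH = 4000


class Feature(str, Enum):
    """Local sequence features carried by per-residue tracks."""

    SS3 = "SS3"
    DISORDER = "DISORDER"
    TM = "TM"
    SIGNAL = "SIGNAL"
    COIL = "COIL"
    LOWCOMPLEX = "LOWCOMPLEX"
    CONSERVATION = "CONSERVATION"


#: positive-call display letter for each binary feature ('.' = negative)
POSITIVE_SYMBOL = {
    Feature.DISORDER: "*",
    Feature.TM: "H",
    Feature.SIGNAL: "S",
    Feature.COIL: "x",
    Feature.LOWCOMPLEX: "x",
}

#: allowed symbols per feature; SS3 includes '.' as an explicit no-call so
#: that coil-only secondary-structure predictors fit the same dialect
FEATURE_ALPHABET = {
    Feature.SS3: set("HEC."),
    Feature.DISORDER: set("*."),
    Feature.TM: set("H."),
    Feature.SIGNAL: set("S."),
    Feature.COIL: set("x."),
    Feature.LOWCOMPLEX: set("x."),
    Feature.CONSERVATION: set("0123456789"),
}


class Collection(str, Enum):
    SPROT = "SPROT"
    NR = "NR"
    GO = "GO"
    PDB = "PDB"
    SCOP = "SCOP"
    CDD = "CDD"


class Method(str, Enum):
    BLAST = "BLAST"
    RPSBLAST = "RPSBLAST"
    HHPRED = "HHPRED"


@dataclass(frozen=True)
class QuerySequence:
    """A validated query protein sequence (1-based residue indexing)."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("query id must be non-empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ParseError(
                f"query contains non-amino-acid characters: {sorted(bad)}"
            )
        if len(self.residues) < MIN_QUERY_LENGTH:
            raise ValidationError(
                f"query length {len(self.residues)} below minimum 30 amino acids"
            )
        if len(self.residues) > MAX_QUERY_LENGTH:
            raise ValidationError(
                f"query length {len(self.residues)} above maximum 4000 amino acids"
            )


@dataclass(frozen=True)
class PredictionTrack:
    """One predictor's per-residue symbol string for one feature."""

    predictor: str
    feature: Feature
    symbols: str

    def validate(self, query: QuerySequence) -> "PredictionTrack":
        if len(self.symbols) != query.length:
            raise ValidationError(
                f"track from {self.predictor}: {len(self.symbols)} symbols "
                f"vs query length {query.length}"
            )
        alphabet = FEATURE_ALPHABET[self.feature]
        bad = set(self.symbols) - alphabet
        if bad:
            raise ValidationError(
                f"track from {self.predictor}: symbols {sorted(bad)} not in "
                f"{self.feature.value} alphabet"
            )
        return self


@dataclass(frozen=True)
class HitRecord:
    """One row of a homology-search table (BLAST outfmt-6-like dialect)."""

    subject_id: str
    collection: Collection
    method: Method
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity_pct: float
    q_cov_pct: float
    s_cov_pct: float
    evalue: Optional[float] = None
    probability_pct: Optional[float] = None
    annotation: str = ""
    go_terms: tuple = ()  # tuple of (term_id, evidence_code)
    ec_numbers: tuple = ()  # tuple of EC strings

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end):
            raise ValidationError(
                f"hit {self.subject_id}: inverted or non-positive query range "
                f"{self.q_start}-{self.q_end}"
            )
        if not (1 <= self.s_start <= self.s_end):
            raise ValidationError(
                f"hit {self.subject_id}: inverted or non-positive subject range "
                f"{self.s_start}-{self.s_end}"
            )
        for name in ("identity_pct", "q_cov_pct", "s_cov_pct", "probability_pct"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(f"hit {self.subject_id}: {name}={v} outside [0,100]")
        if self.evalue is not None and self.evalue <= 0:
            raise ValidationError(f"hit {self.subject_id}: e-value must be positive")


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path) -> QuerySequence:
    """Read a single-record FASTA (or headerless plain-text) query.

    Plain text without a ``>`` header is accepted and assigned id "query".
    Whitespace is ignored; residues are upper-cased before validation.
    """
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) == 0:
            raise ParseError(f"{path}: no FASTA records")
        if len(records) > 1:
            raise ParseError(f"{path}: expected a single record, found {len(records)}")
        rec = records[0]
        return QuerySequence(id=rec.id or "query", residues=str(rec.seq).upper())
    residues = "".join(text.split()).upper()
    if not residues:
        raise ParseError(f"{path}: empty query")
    return QuerySequence(id="query", residues=residues)


def _read_tsv(path: str | Path, required: list[str]) -> list[tuple[int, dict]]:
    """Read a headered TSV; returns (1-based line number, row dict) pairs."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        values = line.split("\t")
        if len(values) < len(header):
            values += [""] * (len(header) - len(values))
        rows.append((lineno, dict(zip(header, values))))
    return rows


TRACK_COLUMNS = ["predictor", "feature", "symbols"]


def read_tracks(path: str | Path, query: QuerySequence) -> list[PredictionTrack]:
    """Read tracks.tsv and validate every track against the query."""
    tracks = []
    for lineno, row in _read_tsv(path, TRACK_COLUMNS):
        try:
            feature = Feature(row["feature"])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: unknown feature {row['feature']!r}"
            ) from None
        track = PredictionTrack(row["predictor"], feature, row["symbols"])
        track.validate(query)
        tracks.append(track)
    return tracks


HIT_COLUMNS = [
    "subject_id", "method", "evalue", "probability_pct", "identity_pct",
    "q_start", "q_end", "s_start", "s_end", "q_cov_pct", "s_cov_pct",
    "annotation", "go_terms", "ec_numbers",
]


def _parse_go_terms(cell: str) -> tuple:
    # "GO:0003924|IDA;GO:0005525|IEA" -> ((term, code), ...)
    pairs = []
    for item in cell.split(";"):
        if not item:
            continue
        term, _, code = item.partition("|")
        pairs.append((term, code))
    return tuple(pairs)


def read_hits(path: str | Path, collection: Collection) -> list[HitRecord]:
    """Read a hits_<collection>.tsv table into validated HitRecords.

    Trailing optional columns (evalue, probability_pct, annotation,
    go_terms, ec_numbers) may be empty strings, meaning absent.
    """
    hits = []
    for lineno, row in _read_tsv(path, HIT_COLUMNS):
        try:
            hits.append(_parse_hit_row(row, collection))
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def _parse_hit_row(row: dict, collection: Collection) -> HitRecord:
    def opt_float(cell: str) -> Optional[float]:
        return float(cell) if cell != "" else None

    return HitRecord(
        subject_id=row["subject_id"],
        collection=collection,
        method=Method(row["method"]),
        evalue=opt_float(row["evalue"]),
        probability_pct=opt_float(row["probability_pct"]),
        identity_pct=float(row["identity_pct"]),
        q_start=int(row["q_start"]),
        q_end=int(row["q_end"]),
        s_start=int(row["s_start"]),
        s_end=int(row["s_end"]),
        q_cov_pct=float(row["q_cov_pct"]),
        s_cov_pct=float(row["s_cov_pct"]),
        annotation=row["annotation"],
        go_terms=_parse_go_terms(row["go_terms"]),
        ec_numbers=tuple(e for e in row["ec_numbers"].split(";") if e),
    )


def read_go_edges(path: str | Path) -> set[tuple[str, str]]:
    """Read go_edges.tsv: one (child_term, parent_term) pair per row."""
    edges = set()
    for lineno, row in _read_tsv(path, ["child_term", "parent_term"]):
        if not row["child_term"] or not row["parent_term"]:
            raise ParseError(f"{path}:{lineno}: empty term id")
        edges.add((row["child_term"], row["parent_term"]))
    return edges


EC_SOURCES = {"TRANSFER", "EZYPRED", "EFICAZ"}


def read_ec_evidence(path: str | Path) -> list[dict]:
    """Read ec_evidence.tsv rows: source, ec, confidence (may be empty/LOW)."""
    records = []
    for lineno, row in _read_tsv(path, ["source", "ec", "confidence"]):
        if row["source"] not in EC_SOURCES:
            raise ParseError(f"{path}:{lineno}: unknown source {row['source']!r}")
        conf: object
        cell = row["confidence"]
        if cell == "" or cell == "LOW":
            conf = cell or None
        else:
            try:
                conf = float(cell)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad confidence {cell!r}") from None
        records.append({"source": row["source"], "ec": row["ec"], "confidence": conf,
                        "subject_id": row.get("subject_id", "")})
    return records


def read_alignments(path: str | Path, query: QuerySequence) -> dict[str, str]:
    """Read alignments_nr.tsv: hit_id -> aligned string over query positions.

    Each aligned string has exactly one character per query residue: the hit
    residue aligned there, or '-' where the hit has a gap.
    """
    aligned = {}
    for lineno, row in _read_tsv(path, ["hit_id", "aligned"]):
        if len(row["aligned"]) != query.length:
            raise ParseError(
                f"{path}:{lineno}: aligned string length {len(row['aligned'])} "
                f"vs query length {query.length}"
            )
        aligned[row["hit_id"]] = row["aligned"].upper()
    return aligned


# ---------------------------------------------------------------------------
# writers (bundle side)


def write_tracks(path: str | Path, tracks: list[PredictionTrack]) -> None:
    lines = ["\t".join(TRACK_COLUMNS)]
    for t in tracks:
        lines.append(f"{t.predictor}\t{t.feature.value}\t{t.symbols}")
    Path(path).write_text("\n".join(lines) + "\n")


def _format_hit(hit: HitRecord) -> str:
    def fmt(v: object) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    go = ";".join(f"{t}|{c}" for t, c in hit.go_terms)
    ec = ";".join(hit.ec_numbers)
    cells = [
        hit.subject_id, hit.method.value, fmt(hit.evalue), fmt(hit.probability_pct),
        fmt(hit.identity_pct), str(hit.q_start), str(hit.q_end), str(hit.s_start),
        str(hit.s_end), fmt(hit.q_cov_pct), fmt(hit.s_cov_pct), hit.annotation,
        go, ec,
    ]
    return "\t".join(cells)


def write_hits(path: str | Path, hits: list[HitRecord]) -> None:
    lines = ["\t".join(HIT_COLUMNS)] + [_format_hit(h) for h in hits]
    Path(path).write_text("\n".join(lines) + "\n")


def write_go_edges(path: str | Path, edges: set[tuple[str, str]]) -> None:
    lines = ["child_term\tparent_term"]
    for child, parent in sorted(edges):
        lines.append(f"{child}\t{parent}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ec_evidence(path: str | Path, records: list[dict]) -> None:
    lines = ["source\tec\tconfidence\tsubject_id"]
    for r in records:
        conf = r.get("confidence")
        cell = "" if conf is None else (conf if isinstance(conf, str) else repr(conf))
        lines.append(f"{r['source']}\t{r['ec']}\t{cell}\t{r.get('subject_id', '')}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_alignments(path: str | Path, aligned: dict[str, str]) -> None:
    lines = ["hit_id\taligned"]
    for hit_id in sorted(aligned):
        lines.append(f"{hit_id}\t{aligned[hit_id]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(path: str | Path, query: QuerySequence) -> None:
    chunks = [query.residues[i:i + 60] for i in range(0, query.length, 60)]
    Path(path).write_text(f">{query.id}\n" + "\n".join(chunks) + "\n")


# ---------------------------------------------------------------------------
# report


@dataclass
class Report:
    """The final integrated output for one query.

    Every prediction list is sorted by descending total score with
    deterministic tie-breaks (applied upstream by the scoring modules).
    """

    query: QuerySequence
    consensus_tracks: list = field(default_factory=list)  # PredictionTrack
    homologs: list = field(default_factory=list)          # homology.RankedHomolog
    go_terms: list = field(default_factory=list)          # go_annotation.GoTermScore
    ec_numbers: list = field(default_factory=list)        # ec_annotation.EcPrediction
    is_enzyme: bool = False
    templates: list = field(default_factory=list)         # structure_templates.TemplateScore
    coverage_summary: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def report_to_dict(report: Report) -> dict:
    from . import ec_annotation, go_annotation, homology, structure_templates  # noqa: F401

    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            d = {"__type__": type(obj).__name__}
            for f in dataclasses.fields(obj):
                d[f.name] = enc(getattr(obj, f.name))
            return d
        if isinstance(obj, Enum):
            return obj.value
        if isinstance(obj, (list, tuple)):
            return [enc(x) for x in obj]
        if isinstance(obj, frozenset) or isinstance(obj, set):
            return sorted(enc(x) for x in obj)
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    return enc(report)


def report_from_dict(data: dict) -> Report:
    """Reconstruct a Report from its JSON form (inverse of report_to_dict)."""
    from . import ec_annotation, go_annotation, homology, structure_templates

    registry = {}
    for mod in (ec_annotation, go_annotation, homology, structure_templates):
        for name in dir(mod):
            obj = getattr(mod, name)
            if dataclasses.is_dataclass(obj) and isinstance(obj, type):
                registry[name] = obj
    registry["QuerySequence"] = QuerySequence
    registry["PredictionTrack"] = PredictionTrack
    registry["HitRecord"] = HitRecord
    registry["Report"] = Report

    def dec(obj):
        if isinstance(obj, dict) and "__type__" in obj:
            cls = registry[obj["__type__"]]
            kwargs = {}
            for f in dataclasses.fields(cls):
                if f.name not in obj:
                    continue
                kwargs[f.name] = _coerce(f.type, dec(obj[f.name]))
            return cls(**kwargs)
        if isinstance(obj, dict):
            return {k: dec(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [dec(x) for x in obj]
        return obj

    return dec(data)


_ENUMS = {}


def _coerce(type_hint, value):
    """Re-wrap enum values and tuples lost in JSON round-tripping."""
    if not _ENUMS:
        from . import ec_annotation, homology, structure_templates
        for e in (Feature, Collection, Method, homology.Tier,
                  homology.Direction, homology.RbhStatus):
            _ENUMS[e.__name__] = e
    hint = str(type_hint)
    if isinstance(value, str):
        for e in _ENUMS.values():
            if e.__name__ in hint:
                try:
                    return e(value)
                except ValueError:
                    pass
    if isinstance(value, list) and ("tuple" in hint or "Tuple" in hint
                                    or "set" in hint or "frozenset" in hint):
        items = [tuple(v) if isinstance(v, list) else v for v in value]
        if "frozenset" in hint or "set" in hint:
            return frozenset(items) if "frozenset" in hint else set(items)
        return tuple(items)
    return value


def _wrap_blocks(query: QuerySequence, tracks: list[PredictionTrack],
                 width: int = 60) -> list[str]:
    """Render sequence + track lines in aligned equal-width blocks."""
    lines = []
    label_w = max([len("sequence")] + [len(t.feature.value) for t in tracks]) + 2
    for start in range(0, query.length, width):
        stop = min(start + width, query.length)
        lines.append(f"{'':<{label_w}}{start + 1}")
        lines.append(f"{'sequence':<{label_w}}{query.residues[start:stop]}")
        for t in tracks:
            lines.append(f"{t.feature.value:<{label_w}}{t.symbols[start:stop]}")
        lines.append("")
    return lines


def write_report(report: Report, json_path: str | Path,
                 text_path: str | Path) -> None:
    """Write the loss-less JSON report and the aligned text summary."""
    Path(json_path).write_text(
        json.dumps(report_to_dict(report), indent=1, sort_keys=True) + "\n")
    Path(text_path).write_text(render_text_summary(report))


def read_report(json_path: str | Path) -> Report:
    return report_from_dict(json.loads(Path(json_path).read_text()))


def render_text_summary(report: Report) -> str:
    q = report.query
    out = [f"Query: {q.id} ({q.length} residues)", ""]
    out.append("== Section I: consensus local sequence features ==")
    if report.consensus_tracks:
        out.extend(_wrap_blocks(q, report.consensus_tracks))
    else:
        out.append("none detected")
        out.append("")
    out.append("== Section II: function prediction ==")
    if report.homologs:
        out.append("Closest confident homologs (Swiss-Prot):")
        for h in report.homologs:
            out.append(f"  {h.subject_id}  score={h.score.total}  "
                       f"tier={h.score.tier.value}  {h.annotation}")
    else:
        out.append("homologs: none detected")
    if report.go_terms:
        out.append("GO terms:")
        for g in report.go_terms:
            out.append(f"  {g.term}  score={g.total}  tier={g.tier.value}")
    else:
        out.append("GO terms: none detected")
    if report.ec_numbers:
        out.append(f"EC numbers (enzyme: {'yes' if report.is_enzyme else 'no'}):")
        for e in report.ec_numbers:
            out.append(f"  {e.ec}  score={e.total}  tier={e.tier.value}")
    else:
        out.append("EC numbers: none detected")
    out.append("")
    out.append("== Section III: structure templates ==")
    if report.templates:
        for t in report.templates:
            ranges = ",".join(f"{a}-{b}" for a, b in t.q_range)
            out.append(f"  {t.template_id}  score={t.total}  "
                       f"tier={t.tier.value}  range={ranges}")
        cov = report.coverage_summary
        if cov:
            out.append(f"  residues covered: {cov.get('covered_fraction', 0):.3f}")
    else:
        out.append("none detected")
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# bundle directory


BUNDLE_FILES = {
    "query": "query.fasta",
    "tracks": "tracks.tsv",
    "sprot": "hits_sprot.tsv",
    "nr": "hits_nr.tsv",
    "go": "hits_go.tsv",
    "templates": "hits_templates.tsv",
    "go_edges": "go_edges.tsv",
    "ec_evidence": "ec_evidence.tsv",
    "alignments": "alignments_nr.tsv",
    "proteome_fwd": "proteome_fwd.tsv",
    "proteome_rev": "proteome_rev.tsv",
}


@dataclass
class Bundle:
    """In-memory prediction bundle for one query."""

    query: QuerySequence
    tracks: list = field(default_factory=list)
    sprot_hits: list = field(default_factory=list)
    nr_hits: list = field(default_factory=list)
    go_hits: list = field(default_factory=list)
    template_hits: list = field(default_factory=list)
    go_edges: set = field(default_factory=set)
    ec_evidence: list = field(default_factory=list)
    alignments: dict = field(default_factory=dict)
    proteome_fwd: Optional[list] = None
    proteome_rev: Optional[dict] = None  # hit_id -> ranked HitRecords


def read_bundle(directory: str | Path) -> Bundle:
    """Read a bundle directory; missing optional files yield empty sections."""
    d = Path(directory)
    query = read_fasta(d / BUNDLE_FILES["query"])
    bundle = Bundle(query=query)

    def have(key: str) -> bool:
        return (d / BUNDLE_FILES[key]).exists()

    if have("tracks"):
        bundle.tracks = read_tracks(d / BUNDLE_FILES["tracks"], query)
    if have("sprot"):
        bundle.sprot_hits = read_hits(d / BUNDLE_FILES["sprot"], Collection.SPROT)
    if have("nr"):
        bundle.nr_hits = read_hits(d / BUNDLE_FILES["nr"], Collection.NR)
    if have("go"):
        bundle.go_hits = read_hits(d / BUNDLE_FILES["go"], Collection.GO)
    if have("templates"):
        bundle.template_hits = read_hits(d / BUNDLE_FILES["templates"], Collection.PDB)
    if have("go_edges"):
        bundle.go_edges = read_go_edges(d / BUNDLE_FILES["go_edges"])
    if have("ec_evidence"):
        bundle.ec_evidence = read_ec_evidence(d / BUNDLE_FILES["ec_evidence"])
    if have("alignments"):
        bundle.alignments = read_alignments(d / BUNDLE_FILES["alignments"], query)
    if have("proteome_fwd"):
        bundle.proteome_fwd = read_hits(d / BUNDLE_FILES["proteome_fwd"],
                                        Collection.NR)
    if have("proteome_rev"):
        bundle.proteome_rev = _read_grouped_hits(d / BUNDLE_FILES["proteome_rev"])
    return bundle


def _read_grouped_hits(path: str | Path) -> dict[str, list[HitRecord]]:
    """Reverse-search tables: rows grouped by the searched hit's id."""
    grouped: dict[str, list[HitRecord]] = {}
    for lineno, row in _read_tsv(path, ["searched_id"] + HIT_COLUMNS):
        try:
            hit = _parse_hit_row(row, Collection.NR)
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        grouped.setdefault(row["searched_id"], []).append(hit)
    return grouped


def write_bundle(bundle: Bundle, directory: str | Path) -> None:
    d = Path(directory)
    os.makedirs(d, exist_ok=True)
    write_fasta(d / BUNDLE_FILES["query"], bundle.query)
    if bundle.tracks:
        write_tracks(d / BUNDLE_FILES["tracks"], bundle.tracks)
    if bundle.sprot_hits:
        write_hits(d / BUNDLE_FILES["sprot"], bundle.sprot_hits)
    if bundle.nr_hits:
        write_hits(d / BUNDLE_FILES["nr"], bundle.nr_hits)
    if bundle.go_hits:
        write_hits(d / BUNDLE_FILES["go"], bundle.go_hits)
    if bundle.template_hits:
        write_hits(d / BUNDLE_FILES["templates"], bundle.template_hits)
    if bundle.go_edges:
        write_go_edges(d / BUNDLE_FILES["go_edges"], bundle.go_edges)
    if bundle.ec_evidence:
        write_ec_evidence(d / BUNDLE_FILES["ec_evidence"], bundle.ec_evidence)
    if bundle.alignments:
        write_alignments(d / BUNDLE_FILES["alignments"], bundle.alignments)
    if bundle.proteome_fwd:
        write_hits(d / BUNDLE_FILES["proteome_fwd"], bundle.proteome_fwd)
    if bundle.proteome_rev:
        lines = ["\t".join(["searched_id"] + HIT_COLUMNS)]
        for searched_id in sorted(bundle.proteome_rev):
            for hit in bundle.proteome_rev[searched_id]:
                lines.append(f"{searched_id}\t{_format_hit(hit)}")
        (d / BUNDLE_FILES["proteome_rev"]).write_text("\n".join(lines) + "\n")
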