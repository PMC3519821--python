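"""Combining enzyme-classification evidence into scored EC predictions.

Three evidence sources are merged: EC numbers transferred from scored
Swiss-Prot homologs, a predictor that resolves only the first two levels
of the EC hierarchy (Ezypred-style), and a predictor that resolves all
four levels with a stated confidence (EFICAz-style).  Because the sources
predict to different depths, two EC numbers *agree* when they are equal on
every level both of them specify — so 1.1.1.1 agrees with 1.1.-.-.

Points: homolog transfer contributes 1/2/3 depending on the transferring
hit's homolog score (6-8 / 8-10 / >=10); +1 when at least three distinct
Swiss-Prot hits carry an agreeing EC; +2 when the two-level predictor
agrees; and 2-4 points from the four-level predictor's confidence.  Tiers
sit at 7/5/3 points, and a query is called an enzyme when any prediction
reaches the 3-point 'probable' cut.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from .homology import Tier, TierScheme, assign_tier
from .iofmt import ValidationError

EC_TIERS = TierScheme(very=7, confident=5, probable=3)

_EC_RE = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass(frozen=True)
class EcNumber:
    """A four-level EC code; trailing '-' levels are unspecified."""

    levels: tuple  # four entries, int or None

    def __post_init__(self) -> None:
        if len(self.levels) != 4:
            raise ValidationError("EC number must have four levels")
        seen_gap = False
        for lv in self.levels:
            if lv is None:
                seen_gap = True
            elif seen_gap:
                raise ValidationError(
                    f"{self}: unspecified levels allowed only as a suffix")
            elif not (isinstance(lv, int) and lv > 0):
                raise ValidationError(f"EC level {lv!r} must be a positive integer")
        if self.levels[0] is None:
            raise ValidationError("EC number must specify at least the top level")

    @classmethod
    def parse(cls, text: str) -> "EcNumber":
        m = _EC_RE.match(text.strip())
        if not m:
            raise ValidationError(f"malformed EC number {text!r}")
        return cls(tuple(None if g == "-" else int(g) for g in m.groups()))

    @property
    def specified_depth(self) -> int:
        return sum(1 for lv in self.levels if lv is not None)

    def __str__(self) -> str:
        return ".".join("-" if lv is None else str(lv) for lv in self.levels)


def ec_agrees(a: EcNumber, b: EcNumber) -> bool:
    """True when the numbers match on every level specified in both."""
    return all(x == y for x, y in zip(a.levels, b.levels)
               if x is not None and y is not None)


@dataclass(frozen=True)
class EcTransfer:
    """An EC number carried by a scored Swiss-Prot homolog."""

    ec: EcNumber
    homolog_score: float
    subject_id: str = ""


@dataclass(frozen=True)
class EcPrediction:
    ec: EcNumber
    points_transfer: float
    points_consensus: float
    points_ezypred: float
    points_eficaz: float
    total: float
    tier: Tier
    sources: frozenset = frozenset()


def _transfer_points(homolog_score: float) -> int:
    if homolog_score >= 10:
        return 3
    if homolog_score >= 8:
        return 2
    if homolog_score >= 6:
        return 1
    return 0


def _eficaz_points(confidence: Union[float, str]) -> float:
    if confidence == "LOW":
        return 2.0
    if not isinstance(confidence, (int, float)):
        raise ValidationError(f"bad four-level predictor confidence {confidence!r}")
    if not (0.0 <= confidence <= 1.0):
        raise ValidationError(
            f"four-level predictor confidence {confidence} outside [0,1]")
    if confidence >= 0.9:
        return 4.0
    if confidence >= 0.8:
        return 3.5
    if confidence >= 0.7:
        return 3.0
    if confidence >= 0.6:
        return 2.5
    return 2.0  # below 0.6: treated like an unquantified low-confidence call


def _dedupe_candidates(candidates: list[EcNumber]) -> list[EcNumber]:
    """Keep the most specific representative of each agreeing group."""
    kept: list[EcNumber] = []
    for ec in sorted(set(candidates),
                     key=lambda e: (-e.specified_depth, str(e))):
        if not any(ec_agrees(ec, k) for k in kept):
            kept.append(ec)
    return kept


def combine_ec_evidence(
    transfers: list[EcTransfer],
    ezypred: Optional[EcNumber] = None,
    eficaz: Optional[tuple[EcNumber, Union[float, str]]] = None,
    scheme: TierScheme = EC_TIERS,
) -> list[EcPrediction]:
    """Merge the three evidence sources into ranked EC predictions."""
    candidates = [t.ec for t in transfers]
    if ezypred is not None:
        candidates.append(ezypred)
    if eficaz is not None:
        candidates.append(eficaz[0])
    predictions = []
    for ec in _dedupe_candidates(candidates):
        agreeing = [t for t in transfers if ec_agrees(ec, t.ec)]
        p_transfer = max((_transfer_points(t.homolog_score) for t in agreeing),
                         default=0)
        distinct = {t.subject_id or f"#{i}" for i, t in enumerate(agreeing)}
        p_cons = 1.0 if len(distinct) >= 3 else 0.0
        p_ezy = 2.0 if (ezypred is not None and ec_agrees(ec, ezypred)) else 0.0
        p_efi = 0.0
        if eficaz is not None and ec_agrees(ec, eficaz[0]):
            p_efi = _eficaz_points(eficaz[1])
        sources = set()
        if agreeing:
            sources.add("TRANSFER")
        if p_ezy:
            sources.add("EZYPRED")
        if p_efi:
            sources.add("EFICAZ")
        total = p_transfer + p_cons + p_ezy + p_efi
        predictions.append(EcPrediction(
            ec=ec, points_transfer=float(p_transfer), points_consensus=p_cons,
            points_ezypred=p_ezy, points_eficaz=p_efi, total=total,
            tier=assign_tier(total, scheme), sources=frozenset(sources)))
    predictions.sort(key=lambda p: (-p.total, str(p.ec)))
    return predictions


def is_enzyme(predictions: list[EcPrediction],
              scheme: TierScheme = EC_TIERS) -> bool:
    """A query is called an enzyme when any EC prediction is at least probable."""
    return any(p.total >= scheme.probable for p in predictions)


def evidence_from_records(records: list[dict], homolog_scores: dict[str, float]
                          ) -> tuple[list[EcTransfer], Optional[EcNumber],
                                     Optional[tuple[EcNumber, Union[float, str]]]]:
    """Adapt parsed ec_evidence.tsv rows into combine_ec_evidence inputs.

    TRANSFER rows name the Swiss-Prot hit in subject_id and take that
    hit's homolog rubric total; rows naming an unscored hit score 0.
    """
    transfers = []
    ezypred = None
    eficaz = None
    for rec in records:
        ec = EcNumber.parse(rec["ec"])
        if rec["source"] == "TRANSFER":
            score = homolog_scores.get(rec.get("subject_id", ""), 0.0)
            transfers.append(EcTransfer(ec, score, rec.get("subject_id", "")))
        elif rec["source"] == "EZYPRED":
            ezypred = ec
        elif rec["source"] == "EFICAZ":
            conf = rec.get("confidence")
            eficaz = (ec, "LOW" if conf is None else conf)
    return transfers, ezypred, eficaz
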