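"""Regex-based extraction of sex and age labels from sample metadata.

The extractors are precision-first: they only fire on explicit, unambiguous
phrasings ("gender: male", "sex: M", "sex: 1", "age: 29 y", "age (mo): 520",
"Age" / "25 days" characteristics pairs).  Implicit phrasings such as
"patient X (34, F, non-smoker)" are deliberately NOT matched by default —
a missed label can be filled in later by the expression classifier, while a
wrong label poisons its training set.

Fields are searched in :class:`~ale.metadata_model.FieldOrder` order; inside
the characteristics block, pairs whose key names the label ("sex"/"gender",
"age") are inspected first, and the search terminates at the first field
class that yields a label.

Ages are normalized to years.  A unit written in the text (or in the
characteristics key, as in "age (mo)") wins; a bare number gets the species
default unit — years for human, months for rodents — and is flagged as
defaulted.  Values outside a plausible range (0–120 years for human) are
discarded with a warning rather than reported.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import UnknownUnitError
from .metadata_model import (
    DEFAULT_FIELD_ORDER,
    FieldOrder,
    LabelRecord,
    SampleMetadata,
    field_units,
)

logger = logging.getLogger(__name__)

SEX_KEY_RE = re.compile(r"(?:\bsex\b|\bgender\b)", re.IGNORECASE)
AGE_KEY_RE = re.compile(r"\bage\b", re.IGNORECASE)

#: years per unit; days use the Julian year, months are 1/12 year
UNIT_TO_YEARS = {
    "years": 1.0,
    "months": 1.0 / 12.0,
    "weeks": 7.0 / 365.25,
    "days": 1.0 / 365.25,
}

UNIT_SYNONYMS = {
    "y": "years", "yr": "years", "yrs": "years", "year": "years", "years": "years",
    "mo": "months", "mos": "months", "mon": "months", "month": "months", "months": "months",
    "w": "weeks", "wk": "weeks", "wks": "weeks", "week": "weeks", "weeks": "weeks",
    "d": "days", "day": "days", "days": "days",
}


def convert_age(value: float, unit: str) -> float:
    """Convert an age in *unit* to years.  *unit* must already be resolved."""
    try:
        return value * UNIT_TO_YEARS[unit]
    except KeyError:
        raise UnknownUnitError(f"unknown age unit {unit!r}") from None


@dataclass(frozen=True)
class SexLabel:
    value: str  # "male" | "female"
    source: str = "text"
    matched_field: str = ""
    matched_text: str = ""
    confidence: float = 1.0

    def to_record(self, sample_id: str) -> LabelRecord:
        return LabelRecord(
            sample_id, "sex", self.value, "", self.source,
            self.confidence, self.matched_field, self.matched_text,
        )


@dataclass(frozen=True)
class AgeLabel:
    raw_value: float
    raw_unit: str  # "years"|"months"|"weeks"|"days"|"unknown" (as written)
    value_years: float
    unit_was_default: bool = False
    source: str = "text"
    matched_field: str = ""
    matched_text: str = ""
    confidence: float = 1.0

    def to_record(self, sample_id: str) -> LabelRecord:
        return LabelRecord(
            sample_id, "age", repr(self.value_years), self.raw_unit, self.source,
            self.confidence, self.matched_field, self.matched_text,
        )


@dataclass(frozen=True)
class AgeConfig:
    """Species default units, plausibility bounds and the unit synonym table."""

    #: (organism substring, default unit); first match wins
    species_default_unit: tuple[tuple[str, str], ...] = (
        ("mus", "months"),
        ("rattus", "months"),
    )
    fallback_unit: str = "years"
    #: inclusive bounds on the converted age, in years (0 kept: neonates)
    plausible_range_years: tuple[float, float] = (0.0, 120.0)
    unit_synonyms: dict[str, str] = field(default_factory=lambda: dict(UNIT_SYNONYMS))

    def default_unit(self, organism: str) -> str:
        low = organism.lower()
        for substring, unit in self.species_default_unit:
            if substring in low:
                return unit
        return self.fallback_unit


DEFAULT_AGE_CONFIG = AgeConfig()


# ---------------------------------------------------------------------------
# the sex vocabulary (shipped as data so curators can extend it)

@dataclass(frozen=True)
class SexVocabulary:
    """Token -> (sex, confidence).  Single letters and digits only fire when
    the surrounding key is an explicit sex/gender key (0/1 coding: 1=male)."""

    tokens: dict[str, tuple[str, float]]

    def lookup(self, token: str, keyed: bool) -> tuple[str, float] | None:
        hit = self.tokens.get(token.lower())
        if hit is None:
            return None
        if not keyed and (len(token) <= 1 or token.isdigit()):
            return None
        return hit


def load_pattern_table(path: str | Path | None = None) -> SexVocabulary:
    """Load the sex token vocabulary from the shipped (or a custom) TSV."""
    if path is None:
        source = resources.files("ale").joinpath("data/patterns.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    tokens: dict[str, tuple[str, float]] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        if row["label_type"] != "sex":
            continue
        tokens[row["pattern"].lower()] = (row["value_or_capture"], float(row["confidence"]))
    return SexVocabulary(tokens)


DEFAULT_SEX_VOCAB = load_pattern_table()

_SEX_KEYED_RE = re.compile(r"\b(?:sex|gender)\b\s*[:=]?\s*([A-Za-z01]+)", re.IGNORECASE)
_SEX_BARE_RE = re.compile(r"\b(male|female|man|woman)\b", re.IGNORECASE)
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def extract_sex(
    meta: SampleMetadata,
    order: FieldOrder = DEFAULT_FIELD_ORDER,
    vocab: SexVocabulary = DEFAULT_SEX_VOCAB,
) -> SexLabel | None:
    """Extract a sex label, or None.

    Searches field classes in *order*; within characteristics, sex/gender
    keyed pairs first.  The first field class with any match wins and the
    search terminates.  If one field class contains both "male" and "female"
    evidence the record gets no label (contradiction) and a warning is logged.
    """
    for field_class in order.fields:
        found: list[tuple[str, float, str, str]] = []  # value, conf, field, text
        for flabel, key, text in field_units(meta, field_class, SEX_KEY_RE.pattern):
            if key is not None and SEX_KEY_RE.search(key):
                for token in _TOKEN_RE.findall(text):
                    hit = vocab.lookup(token, keyed=True)
                    if hit:
                        found.append((hit[0], hit[1], flabel, f"{key}: {text}"))
            else:
                for m in _SEX_KEYED_RE.finditer(text):
                    hit = vocab.lookup(m.group(1), keyed=True)
                    if hit:
                        found.append((hit[0], hit[1], flabel, m.group(0)))
                for m in _SEX_BARE_RE.finditer(text):
                    hit = vocab.lookup(m.group(1), keyed=False)
                    if hit:
                        found.append((hit[0], hit[1], flabel, m.group(0)))
        if not found:
            continue
        values = {v for v, _, _, _ in found}
        if len(values) > 1:
            logger.warning(
                "sample %s: contradictory sex evidence in %s: %s",
                meta.sample_id, field_class, sorted(values),
            )
            return None
        value, conf, flabel, text = found[0]
        return SexLabel(value, "text", flabel, text, conf)
    return None


# ---------------------------------------------------------------------------
# age

# value side of a characteristics pair: "25", "25 days", "70 years old"
_AGE_VALUE_RE = re.compile(
    r"^\s*(-?\d+(?:\.\d+)?)\s*([A-Za-z]+)?\s*(?:old)?\s*\.?\s*$", re.IGNORECASE
)
# free text: "age: 29 y", "age (mo): 520", "age = 47"
_AGE_FREE_RE = re.compile(
    r"\bage\b\s*(?:\(\s*([A-Za-z]+)\s*\.?\s*\))?\s*[:=]\s*"
    r"(-?\d+(?:\.\d+)?)\s*([A-Za-z]*)",
    re.IGNORECASE,
)


def _unit_from_key(key: str, synonyms: dict[str, str]) -> str | None:
    """A unit written inside the key, as in "age (mo)" or "age in weeks"."""
    for token in _TOKEN_RE.findall(key.lower()):
        if token != "age" and token in synonyms:
            return synonyms[token]
    return None


def _resolve_unit(
    value_token: str | None, key_unit: str | None, synonyms: dict[str, str]
) -> tuple[str | None, bool]:
    """Return (resolved unit or None-for-default, reject).

    A trailing alphabetic token that is not a recognized unit synonym rejects
    the candidate outright: "age: 29 yaers" must not silently become 29 of
    the default unit.
    """
    if value_token:
        token = value_token.lower()
        if token == "old":
            return key_unit, False
        if token in synonyms:
            return synonyms[token], False
        return None, True
    return key_unit, False


def extract_age(
    meta: SampleMetadata,
    order: FieldOrder = DEFAULT_FIELD_ORDER,
    cfg: AgeConfig = DEFAULT_AGE_CONFIG,
) -> AgeLabel | None:
    """Extract an age label normalized to years, or None.

    The first syntactic match terminates the search; if its converted value
    falls outside ``cfg.plausible_range_years`` the label is discarded (with
    a warning) and the sample gets no age.
    """
    for field_class in order.fields:
        for flabel, key, text in field_units(meta, field_class, AGE_KEY_RE.pattern):
            if key is not None and AGE_KEY_RE.search(key):
                m = _AGE_VALUE_RE.match(text)
                if not m:
                    continue
                value = float(m.group(1))
                unit, reject = _resolve_unit(
                    m.group(2), _unit_from_key(key, cfg.unit_synonyms), cfg.unit_synonyms
                )
                matched_text = f"{key}: {text}"
            else:
                m = _AGE_FREE_RE.search(text)
                if not m:
                    continue
                value = float(m.group(2))
                key_unit = (
                    cfg.unit_synonyms.get(m.group(1).lower()) if m.group(1) else None
                )
                trailing = m.group(3) or None
                unit, reject = _resolve_unit(trailing, key_unit, cfg.unit_synonyms)
                if m.group(1) and key_unit is None:
                    reject = True  # parenthesised token that is not a unit
                matched_text = m.group(0)
            if reject:
                logger.warning(
                    "sample %s: unrecognized age unit in %r, no label",
                    meta.sample_id, matched_text,
                )
                continue
            if value < 0:
                continue
            unit_was_default = unit is None
            resolved = unit if unit is not None else cfg.default_unit(meta.organism)
            years = convert_age(value, resolved)
            lo, hi = cfg.plausible_range_years
            if not (lo <= years <= hi):
                logger.warning(
                    "sample %s: age %.4g years outside plausible range %s, discarded",
                    meta.sample_id, years, cfg.plausible_range_years,
                )
                return None
            return AgeLabel(
                raw_value=value,
                raw_unit="unknown" if unit_was_default else resolved,
                value_years=years,
                unit_was_default=unit_was_default,
                matched_field=flabel,
                matched_text=matched_text,
            )
    return None
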