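"""Domain types for multiple-cause-of-death (MCOD) records.

A death certificate carries up to 20 entity-axis ICD-10 condition codes
(the "health conditions associated with death"), one underlying-cause
code, and a set of demographic and circumstance attributes. Records are
aggregated to disease categories through a :class:`CategoryMap`, which is
user-supplied configuration: the full study-scale map has 346 categories,
while the bundled demo map covers ~30 categories sufficient to exercise
the pipeline.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ICD10_PATTERN",
    "SEX_LEVELS",
    "RACE_LEVELS",
    "EDUCATION_LEVELS",
    "MARITAL_LEVELS",
    "RESIDENT_LEVELS",
    "PLACE_LEVELS",
    "MANNER_LEVELS",
    "DEFAULT_AGE_CUTS",
    "RawDeathRecord",
    "CategoryMap",
    "CodedRecord",
    "age_band",
    "is_valid_icd10",
]

#: Entity-axis ICD-10 code shape: letter, two digits, up to two more
#: alphanumerics (e.g. "I251", "J449", "C50").
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]{0,2}$")

MAX_ENTITY_CONDITIONS = 20

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("white", "black", "american_indian", "asian_pacific")
EDUCATION_LEVELS = ("primary", "secondary", "tertiary")
MARITAL_LEVELS = ("married", "widowed", "divorced", "never_married")
RESIDENT_LEVELS = ("local", "nonlocal_us", "foreign")
PLACE_LEVELS = (
    "hospital_inpatient",
    "hospital_outpatient_er",
    "hospital_doa",
    "home",
    "hospice",
    "nursing_home",
    "other",
)
MANNER_LEVELS = ("accident", "suicide", "homicide", "natural")

#: Default age bands: <18, 18-40, 41-64, 65-84, >=85 years.
DEFAULT_AGE_CUTS = (18, 41, 65, 85)


def is_valid_icd10(code: str) -> bool:
    """True when *code* matches the entity-axis ICD-10 shape."""
    return bool(ICD10_PATTERN.match(code))


def age_band(age_years: int | None, cuts: Sequence[int] = DEFAULT_AGE_CUTS) -> str | None:
    """Label the half-open age band containing *age_years*.

    ``cuts`` are ascending lower bounds of the interior bands; the default
    produces ``<18``, ``18-40``, ``41-64``, ``65-84`` and ``85+``. Missing
    age maps to ``None``.
    """
    if age_years is None:
        return None
    cuts = tuple(cuts)
    if age_years < cuts[0]:
        return f"<{cuts[0]}"
    for lo, hi in zip(cuts, cuts[1:]):
        if lo <= age_years < hi:
            return f"{lo}-{hi - 1}"
    return f"{cuts[-1]}+"


@dataclass(frozen=True)
class RawDeathRecord:
    """One parsed death certificate."""

    record_id: str
    data_year: int
    age_years: int | None
    sex: str
    race: str
    education: str | None
    marital: str | None
    resident_status: str
    place_of_death: str | None
    manner: str | None
    underlying_cause: str
    entity_conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.entity_conditions) > MAX_ENTITY_CONDITIONS:
            raise ValueError(
                f"record {self.record_id!r}: {len(self.entity_conditions)} entity "
                f"conditions exceed the {MAX_ENTITY_CONDITIONS}-code certificate limit"
            )
        if self.age_years is not None and not (0 <= self.age_years <= 130):
            raise ValueError(
                f"record {self.record_id!r}: age {self.age_years} outside [0, 130]"
            )
        for code in (self.underlying_cause, *self.entity_conditions):
            if not is_valid_icd10(code):
                raise ValueError(
                    f"record {self.record_id!r}: malformed ICD-10 code {code!r}"
                )


class UnmappedCodeError(KeyError):
    """Raised when a code matches no rule and the map's policy is ``error``."""


@dataclass(frozen=True)
class CategoryMap:
    """Ordered prefix rules aggregating ICD-10 codes into disease categories.

    Lookup is deterministic: the longest matching prefix wins, with ties
    (equal-length prefixes) broken by rule order. ``fallback_policy``
    decides what happens when no rule matches: ``"error"`` raises,
    ``"other_bucket"`` returns the label ``"other"``.
    """

    rules: tuple[tuple[str, str], ...]
    fallback_policy: str = "other_bucket"
    _by_prefix: dict = field(init=False, repr=False, compare=False)

    OTHER_LABEL = "other"

    def __post_init__(self) -> None:
        if self.fallback_policy not in ("error", "other_bucket"):
            raise ValueError(f"unknown fallback_policy {self.fallback_policy!r}")
        by_prefix: dict[str, str] = {}
        for prefix, label in self.rules:
            # first rule wins among equal prefixes (rule-order tie-break)
            by_prefix.setdefault(prefix, label)
        object.__setattr__(self, "_by_prefix", by_prefix)

    @property
    def category_vocabulary(self) -> tuple[str, ...]:
        """Unique labels in first-appearance rule order; the ``other``
        bucket, when enabled, is appended last."""
        seen: dict[str, None] = {}
        for _, label in self.rules:
            seen.setdefault(label, None)
        if self.fallback_policy == "other_bucket":
            seen.setdefault(self.OTHER_LABEL, None)
        return tuple(seen)

    def lookup(self, code: str) -> str:
        """Map one ICD-10 code to its disease-category label."""
        for n in range(len(code), 0, -1):
            label = self._by_prefix.get(code[:n])
            if label is not None:
                return label
        if self.fallback_policy == "other_bucket":
            return self.OTHER_LABEL
        raise UnmappedCodeError(f"no category rule matches ICD-10 code {code!r}")

    @classmethod
    def from_csv(cls, path: str | Path, fallback_policy: str = "other_bucket") -> "CategoryMap":
        """Load ``prefix,label`` rows (header optional) from a CSV file."""
        rules: list[tuple[str, str]] = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                if row[0].strip().lower() == "prefix":
                    continue
                rules.append((row[0].strip(), row[1].strip()))
        return cls(rules=tuple(rules), fallback_policy=fallback_policy)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryMap":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        rules = tuple((str(p), str(l)) for p, l in cfg["rules"])
        return cls(rules=rules, fallback_policy=cfg.get("fallback_policy", "other_bucket"))

    @classmethod
    def load(cls, path: str | Path, **kwargs) -> "CategoryMap":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            return cls.from_yaml(path)
        return cls.from_csv(path, **kwargs)


@dataclass(frozen=True)
class CodedRecord:
    """A raw record plus its deduplicated disease-category set.

    ``multimorbid`` is 1 exactly when the record carries two or more
    *different* disease categories; duplicate codes that aggregate to one
    category count once.
    """

    raw: RawDeathRecord
    categories: frozenset[str]
    underlying_category: str
    multimorbid: int
    age_group: str | None

    def __post_init__(self) -> None:
        expected = int(len(self.categories) >= 2)
        if self.multimorbid != expected:
            raise ValueError("multimorbid flag inconsistent with category count")

    @property
    def usable(self) -> bool:
        """Records without any health condition are dropped by the study filter."""
        return len(self.categories) >= 1

    @property
    def record_id(self) -> str:
        return self.raw.record_id
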