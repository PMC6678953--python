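"""Cluster and whole-population profiling of coded death records.

Conventions follow standard mortality-table practice: categorical
attributes are tabulated as count (percent) with the percent computed
over records whose level is *known* (the non-missing denominator), while
binary condition indicators — prevalence of a disease category,
multimorbidity — are computed over the full cluster size. Continuous
attributes are reported as mean (sample SD). Cluster means are compared
against the rest of the population with a two-sided Welch t-test; with
an a-priori significance threshold of p < 0.01. A one-sample mode
testing the cluster against a fixed global mean is available as well.

Percentages are rounded half-up: two decimals in tables, one decimal in
prose-style exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import CodedRecord

__all__ = [
    "TestResult",
    "LevelSummary",
    "AttributeSummary",
    "ClusterProfile",
    "DEFAULT_PROFILE_ATTRIBUTES",
    "round_half_up",
    "percent",
    "categorical_percents",
    "records_frame",
    "summarize_attribute",
    "cluster_mean_test",
    "top_k_conditions",
    "comorbidity_share",
    "profile_clusters",
    "format_population_table",
    "profiles_to_frame",
]

SIGNIFICANCE_LEVEL = 0.01

#: (attribute, kind) pairs profiled by default, mirroring the population
#: characteristics table: demographics, circumstances, condition burden.
DEFAULT_PROFILE_ATTRIBUTES: tuple[tuple[str, str], ...] = (
    ("age_years", "continuous"),
    ("sex", "categorical"),
    ("race", "categorical"),
    ("education", "categorical"),
    ("marital", "categorical"),
    ("resident_status", "categorical"),
    ("place_of_death", "categorical"),
    ("manner", "categorical"),
    ("n_conditions", "continuous"),
    ("multimorbid", "binary"),
)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as printed tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, denominator: float, decimals: int = 2) -> float:
    """count / denominator as a half-up-rounded percentage."""
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * count / denominator, decimals)


def categorical_percents(
    level_counts: dict[str, int], decimals: int = 2
) -> dict[str, float]:
    """Per-level percentages over the non-missing denominator (the sum of
    the level counts themselves)."""
    denom = sum(level_counts.values())
    return {lvl: percent(c, denom, decimals) for lvl, c in level_counts.items()}


@dataclass(frozen=True)
class TestResult:
    t: float
    p: float
    available: bool = True
    alpha: float = SIGNIFICANCE_LEVEL

    @property
    def significant(self) -> bool:
        return self.available and self.p < self.alpha

    @classmethod
    def unavailable(cls) -> "TestResult":
        return cls(t=float("nan"), p=float("nan"), available=False)

    def at_alpha(self, alpha: float) -> "TestResult":
        return TestResult(t=self.t, p=self.p, available=self.available, alpha=alpha)


@dataclass
class LevelSummary:
    level: str
    count: int
    pct: float
    test: TestResult


@dataclass
class AttributeSummary:
    """One attribute within one cluster (or the whole population)."""

    name: str
    kind: str  # continuous | categorical | binary
    n: int  # cluster size
    n_nonmissing: int
    mean: float | None = None
    sd: float | None = None
    count: int | None = None  # binary: number of positives
    pct: float | None = None  # binary: positives / cluster n
    levels: list[LevelSummary] = field(default_factory=list)
    test: TestResult | None = None

    @property
    def available(self) -> bool:
        return self.n_nonmissing > 0


@dataclass
class ClusterProfile:
    cluster_id: int | None  # None = whole population
    n: int
    attributes: dict[str, AttributeSummary]
    top5_conditions: list[tuple[str, float]]
    top5_underlying: list[tuple[str, float]]
    multimorbid_pct: float
    mean_conditions: float


def records_frame(records: Sequence[CodedRecord]) -> pd.DataFrame:
    """Flatten coded records into the DataFrame profiling operates on."""
    rows = []
    for r in records:
        raw = r.raw
        rows.append(
            {
                "record_id": raw.record_id,
                "data_year": raw.data_year,
                "age_years": np.nan if raw.age_years is None else float(raw.age_years),
                "sex": raw.sex,
                "race": raw.race,
                "education": raw.education,
                "marital": raw.marital,
                "resident_status": raw.resident_status,
                "place_of_death": raw.place_of_death,
                "manner": raw.manner,
                "underlying_category": r.underlying_category,
                "categories": r.categories,
                "n_conditions": float(len(r.categories)),
                "multimorbid": float(r.multimorbid),
                "age_group": r.age_group,
            }
        )
    return pd.DataFrame(rows)


def cluster_mean_test(
    cluster_values: np.ndarray,
    complement_values: np.ndarray | None = None,
    mode: str = "welch",
    global_mean: float | None = None,
) -> TestResult:
    """Two-sided test of a cluster mean against the rest of the population.

    ``welch`` (default): two-sample Welch t-test of cluster vs
    complement. ``global_constant``: one-sample t-test of the cluster
    values against a fixed global mean — the literal reading of testing
    "against the global mean". Either way the statistic is flagged
    unavailable when fewer than two non-missing values exist on a side.
    """
    x = np.asarray(cluster_values, dtype=float)
    x = x[~np.isnan(x)]
    if mode == "welch":
        if complement_values is None:
            raise ValueError("welch mode needs complement values")
        y = np.asarray(complement_values, dtype=float)
        y = y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            return TestResult.unavailable()
        t, p = stats.ttest_ind(x, y, equal_var=False)
    elif mode == "global_constant":
        if global_mean is None:
            raise ValueError("global_constant mode needs the global mean")
        if len(x) < 2:
            return TestResult.unavailable()
        t, p = stats.ttest_1samp(x, popmean=global_mean)
    else:
        raise ValueError(f"unknown test mode {mode!r}")
    if not np.isfinite(t):
        return TestResult.unavailable()
    return TestResult(t=float(t), p=float(p))


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")


def summarize_attribute(
    frame: pd.DataFrame,
    cluster_mask: np.ndarray,
    attribute: str,
    kind: str,
    test_mode: str = "welch",
    with_tests: bool = True,
) -> AttributeSummary:
    """Summarize one attribute over the records selected by *cluster_mask*.

    Categorical percentages use the non-missing denominator; binary
    indicators use the full cluster size. Tests compare the cluster to
    its complement; they are skipped (``with_tests=False``) for the
    whole-population row, where the complement is empty.
    """
    if attribute not in frame.columns:
        raise KeyError(f"attribute {attribute!r} not present")
    mask = np.asarray(cluster_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cannot summarize an empty cluster")
    col = frame[attribute]

    if kind in ("continuous", "binary"):
        values = col.to_numpy(dtype=float)
        x = values[mask]
        xr = x[~np.isnan(x)]
        test = (
            cluster_mean_test(x, values[~mask], mode=test_mode,
                              global_mean=float(np.nanmean(values)))
            if with_tests
            else TestResult.unavailable()
        )
        summary = AttributeSummary(
            name=attribute, kind=kind, n=n, n_nonmissing=len(xr), test=test
        )
        if len(xr) == 0:
            return summary  # flagged unavailable
        summary.mean = float(xr.mean())
        summary.sd = _sample_sd(xr)
        if kind == "binary":
            summary.count = int(xr.sum())
            summary.pct = percent(summary.count, n)  # full-cluster denominator
        return summary

    if kind != "categorical":
        raise ValueError(f"unknown attribute kind {kind!r}")

    sub = col[mask]
    known = sub.dropna()
    counts = known.value_counts().sort_index()
    denom = int(counts.sum())
    summary = AttributeSummary(name=attribute, kind=kind, n=n, n_nonmissing=denom)
    if denom == 0:
        return summary
    for level, cnt in counts.items():
        test = None
        if with_tests:
            indicator = (col == level).where(col.notna(), np.nan).astype(float)
            values = indicator.to_numpy()
            test = cluster_mean_test(
                values[mask], values[~mask], mode=test_mode,
                global_mean=float(np.nanmean(values)),
            )
        summary.levels.append(
            LevelSummary(
                level=str(level),
                count=int(cnt),
                pct=percent(int(cnt), denom),
                test=test or TestResult.unavailable(),
            )
        )
    return summary


def top_k_conditions(
    frame: pd.DataFrame,
    cluster_mask: np.ndarray,
    k: int = 5,
    which: str = "entity_conditions",
) -> list[tuple[str, float]]:
    """Top-k disease categories in a cluster with prevalence percents.

    ``entity_conditions``: share of cluster records carrying the
    category; ``underlying_cause``: share with it as underlying cause.
    Sorted by descending prevalence, ties alphabetically; prevalence is
    over the full cluster size.
    """
    mask = np.asarray(cluster_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cluster is empty")
    if which == "entity_conditions":
        counts: dict[str, int] = {}
        for cats in frame.loc[mask, "categories"]:
            for c in cats:
                counts[c] = counts.get(c, 0) + 1
    elif which == "underlying_cause":
        counts = frame.loc[mask, "underlying_category"].value_counts().to_dict()
    else:
        raise ValueError(f"unknown ranking source {which!r}")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return [(cat, percent(cnt, n)) for cat, cnt in ranked]


def comorbidity_share(
    frame: pd.DataFrame, category: str, decimals: int = 1
) -> tuple[int, int, float]:
    """Among records carrying *category*: how many also carry at least one
    other condition. Returns (n_with_category, n_with_other, percent)."""
    has = frame["categories"].map(lambda cats: category in cats)
    with_cat = frame[has]
    n_cat = len(with_cat)
    if n_cat == 0:
        raise ValueError(f"no record carries category {category!r}")
    n_other = int((with_cat["n_conditions"] >= 2).sum())
    return n_cat, n_other, percent(n_other, n_cat, decimals)


def profile_clusters(
    frame: pd.DataFrame,
    labels: np.ndarray,
    attributes: Sequence[tuple[str, str]] = DEFAULT_PROFILE_ATTRIBUTES,
    test_mode: str = "welch",
    bonferroni: bool = False,
) -> tuple[list[ClusterProfile], ClusterProfile]:
    """Per-cluster profiles (size-descending) plus the whole-population row.

    With ``bonferroni=True`` the significance flags are recomputed at
    alpha / (number of cluster-level tests); the raw p-values are kept
    either way.
    """
    labels = np.asarray(labels)
    if len(labels) != len(frame):
        raise ValueError("labels must align one-to-one with records")

    def _build(mask: np.ndarray, cid: int | None, with_tests: bool) -> ClusterProfile:
        attrs = {
            name: summarize_attribute(frame, mask, name, kind,
                                      test_mode=test_mode, with_tests=with_tests)
            for name, kind in attributes
        }
        mm = summarize_attribute(frame, mask, "multimorbid", "binary", with_tests=False)
        return ClusterProfile(
            cluster_id=cid,
            n=int(mask.sum()),
            attributes=attrs,
            top5_conditions=top_k_conditions(frame, mask, 5, "entity_conditions"),
            top5_underlying=top_k_conditions(frame, mask, 5, "underlying_cause"),
            multimorbid_pct=mm.pct if mm.pct is not None else float("nan"),
            mean_conditions=float(frame.loc[mask, "n_conditions"].mean()),
        )

    ids, sizes = np.unique(labels, return_counts=True)
    single = len(ids) == 1  # complement empty -> tests undefined
    order = sorted(zip(ids, sizes), key=lambda t: (-t[1], t[0]))
    profiles = [
        _build(labels == cid, int(cid), with_tests=not single) for cid, _ in order
    ]
    everyone = np.ones(len(frame), dtype=bool)
    global_profile = _build(everyone, None, with_tests=False)

    if bonferroni:
        n_tests = sum(
            (len(s.levels) if s.kind == "categorical" else 1)
            for p in profiles
            for s in p.attributes.values()
        )
        alpha = SIGNIFICANCE_LEVEL / max(n_tests, 1)
        for p in profiles:
            for s in p.attributes.values():
                if s.test is not None:
                    s.test = s.test.at_alpha(alpha)
                for lvl in s.levels:
                    lvl.test = lvl.test.at_alpha(alpha)
    return profiles, global_profile


_TABLE_ROWS: tuple[tuple[str, str, str], ...] = (
    ("age_years", "continuous", "Age at death (years)"),
    ("sex", "categorical", "Sex"),
    ("race", "categorical", "Race"),
    ("education", "categorical", "Education Level"),
    ("marital", "categorical", "Marital Status"),
    ("resident_status", "categorical", "Resident Status"),
    ("place_of_death", "categorical", "Place of Death"),
    ("manner", "categorical", "Manner of Death"),
    ("n_conditions", "continuous", "Different Health Conditions associated with Death"),
    ("multimorbid", "binary", "Multimorbid"),
)

_LEVEL_TITLES = {
    "female": "Female", "male": "Male",
    "white": "White", "black": "Black",
    "american_indian": "American Indian", "asian_pacific": "Asian/Pacific Islander",
    "primary": "Primary", "secondary": "Secondary", "tertiary": "Tertiary",
    "married": "Married", "widowed": "Widowed", "divorced": "Divorced",
    "never_married": "Never Married",
    "local": "Local Resident", "nonlocal_us": "Non-Local US Resident",
    "foreign": "Foreign Resident",
    "hospital_inpatient": "Hospital (Inpatient)",
    "hospital_outpatient_er": "Hospital (Outpatient / Emergency Room)",
    "hospital_doa": "Hospital (Dead on Arrival)",
    "home": "Home", "hospice": "Hospice Facility", "nursing_home": "Nursing Home",
    "other": "Other",
    "accident": "Accident", "suicide": "Suicide", "homicide": "Homicide",
    "natural": "Natural",
}


def format_population_table(profile: ClusterProfile) -> str:
    """Render a population profile as a Table-1-style text table:
    ``n (%)`` for categorical levels, ``Mean (SD)`` for continuous rows,
    thousands separators, two-decimal half-up percents."""
    width = 44
    lines = [
        f"Characteristics as reported in {profile.n:,} death records",
        f"{'Person Characteristics':<{width}}n (%) or Mean (SD)",
    ]
    for attr, kind, title in _TABLE_ROWS:
        s = profile.attributes.get(attr)
        if s is None or not s.available:
            continue
        if kind == "continuous":
            lines.append(
                f"{title:<{width}}{round_half_up(s.mean, 2):.2f}"
                f" ({round_half_up(s.sd, 2):.2f})"
            )
        elif kind == "binary":
            lines.append(f"{title:<{width}}{s.count:,} ({s.pct:.2f}%)")
        else:
            lines.append(title)
            for lvl in s.levels:
                name = _LEVEL_TITLES.get(lvl.level, lvl.level)
                lines.append(f"  {name:<{width - 2}}{lvl.count:,} ({lvl.pct:.2f}%)")
    return "\n".join(lines)


def profiles_to_frame(
    profiles: Sequence[ClusterProfile], global_profile: ClusterProfile | None = None
) -> pd.DataFrame:
    """Long-format export: one row per cluster x attribute x level."""
    rows = []
    everything = list(profiles) + ([global_profile] if global_profile else [])
    for p in everything:
        cid = "all" if p.cluster_id is None else p.cluster_id
        for s in p.attributes.values():
            if s.kind == "categorical":
                for lvl in s.levels:
                    rows.append(
                        {
                            "cluster": cid, "n": p.n, "attribute": s.name,
                            "level": lvl.level, "count": lvl.count, "pct": lvl.pct,
                            "mean": None, "sd": None,
                            "t": lvl.test.t if lvl.test.available else None,
                            "p": lvl.test.p if lvl.test.available else None,
                            "significant": lvl.test.significant,
                        }
                    )
            else:
                t = s.test if s.test is not None else TestResult.unavailable()
                rows.append(
                    {
                        "cluster": cid, "n": p.n, "attribute": s.name,
                        "level": None, "count": s.count, "pct": s.pct,
                        "mean": s.mean, "sd": s.sd,
                        "t": t.t if t.available else None,
                        "p": t.p if t.available else None,
                        "significant": t.significant,
                    }
                )
    return pd.DataFrame(rows)
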