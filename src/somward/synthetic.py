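"""Synthetic MCOD-like populations with planted cluster structure.

The generator is a latent-class model: each record belongs to one latent
cluster; given the cluster, each disease category is drawn independently
by its cluster-specific prevalence, demographics come from
cluster-specific categorical distributions, and age from a truncated
normal. It stands in for restricted vital-statistics files, so every
downstream stage (coding, SOM, constrained Ward, profiling) is testable,
and its default configuration is calibrated to the gross margins of the
real mortality data: about three health conditions per record, roughly
78% multimorbidity, and a mean age at death near 73 years.

Generation happens at disease-category level; each category is emitted
as one representative ICD-10 code, so coded records round-trip exactly
through the ingest stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.stats import truncnorm

from .records import (
    EDUCATION_LEVELS,
    MANNER_LEVELS,
    MARITAL_LEVELS,
    PLACE_LEVELS,
    RACE_LEVELS,
    RESIDENT_LEVELS,
    SEX_LEVELS,
    CategoryMap,
    RawDeathRecord,
    is_valid_icd10,
)

__all__ = [
    "ClusterSpec",
    "PopulationSpec",
    "demo_category_map",
    "representative_codes",
    "generate_population",
    "default_benchmark_spec",
    "write_records_csv",
    "write_labels_csv",
]

AGE_MIN, AGE_MAX = 0.0, 130.0


def demo_category_map() -> CategoryMap:
    """The ~35-category demonstration map bundled with the package."""
    path = resources.files("somward.data") / "demo_category_map.csv"
    with resources.as_file(path) as p:
        return CategoryMap.from_csv(p)


def representative_codes(category_map: CategoryMap) -> dict[str, str]:
    """One valid ICD-10 code per category label (first rule's prefix,
    zero-padded to code shape); the fallback bucket gets R99
    (ill-defined cause), which matches no rule by construction."""
    codes: dict[str, str] = {}
    for prefix, label in category_map.rules:
        if label in codes:
            continue
        code = prefix + "0" * max(0, 3 - len(prefix))
        if not is_valid_icd10(code):
            raise ValueError(f"cannot derive a representative code from prefix {prefix!r}")
        codes[label] = code
    if category_map.fallback_policy == "other_bucket":
        codes.setdefault(CategoryMap.OTHER_LABEL, "R99")
    return codes


def _as_prob_vector(probs: dict[str, float], levels: Sequence[str], name: str) -> np.ndarray:
    vec = np.array([probs.get(l, 0.0) for l in levels], dtype=float)
    if (vec < 0).any() or not np.isclose(vec.sum(), 1.0, atol=1e-8):
        raise ValueError(f"{name}: probabilities must be non-negative and sum to 1")
    unknown = set(probs) - set(levels)
    if unknown:
        raise ValueError(f"{name}: unknown levels {sorted(unknown)}")
    return vec


@dataclass
class ClusterSpec:
    """One latent cluster: category prevalences plus attribute distributions."""

    label: str
    weight: float
    condition_prevalence: np.ndarray  # aligned with PopulationSpec.vocabulary
    age_mean: float
    age_sd: float
    sex_probs: dict[str, float]
    race_probs: dict[str, float]
    education_probs: dict[str, float]
    marital_probs: dict[str, float]
    place_probs: dict[str, float]
    manner_probs: dict[str, float]
    underlying_weights: np.ndarray | None = None  # defaults to prevalence
    resident_probs: dict[str, float] | None = None  # defaults to population margin

    def validate(self, n_categories: int) -> list[str]:
        problems = []
        p = np.asarray(self.condition_prevalence, dtype=float)
        if p.shape != (n_categories,):
            problems.append(f"{self.label}: prevalence length {p.shape} != {n_categories}")
        elif (p < 0).any() or (p > 1).any():
            problems.append(f"{self.label}: prevalences outside [0, 1]")
        elif not (p > 0).any():
            problems.append(f"{self.label}: all prevalences zero")
        if self.weight <= 0:
            problems.append(f"{self.label}: non-positive weight")
        if self.age_sd <= 0:
            problems.append(f"{self.label}: non-positive age_sd")
        for name, probs, levels in (
            ("sex_probs", self.sex_probs, SEX_LEVELS),
            ("race_probs", self.race_probs, RACE_LEVELS),
            ("education_probs", self.education_probs, EDUCATION_LEVELS),
            ("marital_probs", self.marital_probs, MARITAL_LEVELS),
            ("place_probs", self.place_probs, PLACE_LEVELS),
            ("manner_probs", self.manner_probs, MANNER_LEVELS),
            ("resident_probs", self.resident_probs or _DEFAULT_RESIDENT, RESIDENT_LEVELS),
        ):
            try:
                _as_prob_vector(probs, levels, f"{self.label}.{name}")
            except ValueError as exc:
                problems.append(str(exc))
        return problems


@dataclass
class PopulationSpec:
    """Full recipe for one synthetic population."""

    n_records: int
    vocabulary: tuple[str, ...]
    clusters: list[ClusterSpec]
    codes: dict[str, str]  # category label -> representative ICD-10 code
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    allow_empty_fraction: float = 0.0
    data_year: int = 2011

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_records < 1:
            problems.append("n_records must be >= 1")
        if not self.clusters:
            problems.append("at least one cluster required")
        w = np.array([c.weight for c in self.clusters], dtype=float)
        if len(w) and not np.isclose(w.sum(), 1.0, atol=1e-6):
            problems.append(f"cluster weights sum to {w.sum():.6f}, expected 1")
        for c in self.clusters:
            problems.extend(c.validate(len(self.vocabulary)))
        for attr, p in self.missingness.items():
            if not (0.0 <= p < 1.0):
                problems.append(f"missingness[{attr}] = {p} outside [0, 1)")
        if not (0.0 <= self.allow_empty_fraction < 1.0):
            problems.append("allow_empty_fraction outside [0, 1)")
        missing_codes = [l for l in self.vocabulary if l not in self.codes]
        if missing_codes:
            problems.append(f"no representative code for categories {missing_codes}")
        if problems:
            raise ValueError("invalid PopulationSpec: " + "; ".join(problems))


def _draw_categorical(rng: np.random.Generator, prob_rows: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw: prob_rows is (n, L); returns (n,) level indices."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0])
    return np.minimum((u[:, None] > cum).sum(axis=1), prob_rows.shape[1] - 1)


def _draw_attribute(
    rng: np.random.Generator,
    z: np.ndarray,
    per_cluster: list[dict[str, float]],
    levels: Sequence[str],
    name: str,
) -> np.ndarray:
    P = np.vstack([_as_prob_vector(p, levels, name) for p in per_cluster])
    idx = _draw_categorical(rng, P[z])
    return np.asarray(levels, dtype=object)[idx]


def generate_population(
    spec: PopulationSpec,
    seed: int | None = None,
) -> tuple[list[RawDeathRecord], np.ndarray]:
    """Draw a full population; returns (records, per-record latent cluster index).

    Deterministic: the same spec and seed yield the identical record
    stream. Records are guaranteed usable (>= 1 condition) by forcing the
    cluster's highest-prevalence category when no condition is drawn,
    unless the record falls in the explicit ``allow_empty_fraction``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_records
    K = len(spec.clusters)
    C = len(spec.vocabulary)

    weights = np.array([c.weight for c in spec.clusters], dtype=float)
    weights = weights / weights.sum()
    z = rng.choice(K, size=n, p=weights)

    # conditions: independent Bernoulli given cluster
    P = np.vstack([np.asarray(c.condition_prevalence, float) for c in spec.clusters])
    X = rng.random((n, C)) < P[z]

    forced_empty = rng.random(n) < spec.allow_empty_fraction
    X[forced_empty] = False
    top_cat = P.argmax(axis=1)
    no_cond = ~X.any(axis=1) & ~forced_empty
    X[no_cond, top_cat[z[no_cond]]] = True

    # underlying cause: drawn from the record's present categories by weight;
    # empty records draw from the cluster's full weight vector.
    W = np.vstack(
        [
            np.asarray(
                c.underlying_weights
                if c.underlying_weights is not None
                else c.condition_prevalence,
                float,
            )
            for c in spec.clusters
        ]
    )
    wrec = W[z] * X
    empty_rows = ~wrec.any(axis=1)
    wrec[empty_rows] = W[z[empty_rows]] + 1e-12
    wrec = wrec / wrec.sum(axis=1, keepdims=True)
    underlying_idx = _draw_categorical(rng, wrec)

    # demographics
    sex = _draw_attribute(rng, z, [c.sex_probs for c in spec.clusters], SEX_LEVELS, "sex")
    race = _draw_attribute(rng, z, [c.race_probs for c in spec.clusters], RACE_LEVELS, "race")
    edu = _draw_attribute(
        rng, z, [c.education_probs for c in spec.clusters], EDUCATION_LEVELS, "education"
    )
    marital = _draw_attribute(
        rng, z, [c.marital_probs for c in spec.clusters], MARITAL_LEVELS, "marital"
    )
    resident = _draw_attribute(
        rng,
        z,
        [c.resident_probs or _DEFAULT_RESIDENT for c in spec.clusters],
        RESIDENT_LEVELS,
        "resident_status",
    )
    place = _draw_attribute(rng, z, [c.place_probs for c in spec.clusters], PLACE_LEVELS, "place")
    manner = _draw_attribute(rng, z, [c.manner_probs for c in spec.clusters], MANNER_LEVELS, "manner")

    # age: truncated normal per cluster, rounded to whole years
    mu = np.array([c.age_mean for c in spec.clusters])[z]
    sd = np.array([c.age_sd for c in spec.clusters])[z]
    a = (AGE_MIN - mu) / sd
    b = (AGE_MAX - mu) / sd
    age = truncnorm.ppf(rng.random(n), a, b, loc=mu, scale=sd)
    age = np.clip(np.rint(age), AGE_MIN, AGE_MAX).astype(int)

    # attribute missingness
    miss_mask = {
        attr: rng.random(n) < p for attr, p in sorted(spec.missingness.items())
    }

    vocab = np.asarray(spec.vocabulary, dtype=object)
    code_of = np.asarray([spec.codes[l] for l in spec.vocabulary], dtype=object)

    def _maybe(attr: str, values, i: int):
        if attr in miss_mask and miss_mask[attr][i]:
            return None
        return values[i]

    records: list[RawDeathRecord] = []
    for i in range(n):
        cond_codes = tuple(code_of[X[i]])
        records.append(
            RawDeathRecord(
                record_id=f"S{i:07d}",
                data_year=spec.data_year,
                age_years=_maybe("age_years", age, i),
                sex=sex[i],
                race=race[i],
                education=_maybe("education", edu, i),
                marital=_maybe("marital", marital, i),
                resident_status=resident[i],
                place_of_death=_maybe("place_of_death", place, i),
                manner=_maybe("manner", manner, i),
                underlying_cause=code_of[underlying_idx[i]],
                entity_conditions=cond_codes,
            )
        )
    return records, z


_DEFAULT_RESIDENT = {"local": 0.809, "nonlocal_us": 0.189, "foreign": 0.002}

# Whole-population attribute margins used as the per-cluster baseline;
# individual clusters override where the cluster's clinical character
# calls for it (e.g. injury clusters die by external manner, geriatric
# clusters in nursing homes).
_BASE = dict(
    sex={"female": 0.4976, "male": 0.5024},
    race={"white": 0.855, "black": 0.1168, "american_indian": 0.0064, "asian_pacific": 0.0218},
    education={"primary": 0.1329, "secondary": 0.5465, "tertiary": 0.3206},
    marital={"married": 0.3802, "widowed": 0.3536, "divorced": 0.1443, "never_married": 0.1219},
    place={
        "hospital_inpatient": 0.3261,
        "hospital_outpatient_er": 0.0676,
        "hospital_doa": 0.0060,
        "home": 0.2779,
        "hospice": 0.0530,
        "nursing_home": 0.2064,
        "other": 0.0630,
    },
    manner={"accident": 0.0626, "suicide": 0.0196, "homicide": 0.0091, "natural": 0.9087},
)

_EXTERNAL_MANNER = {"accident": 0.62, "suicide": 0.22, "homicide": 0.13, "natural": 0.03}

# (label, weight, signature categories, signature prevalences,
#  background scale, age_mean, age_sd, overrides)
# The background scale is the dial separating chronic multi-condition
# deaths (large scale, high multimorbidity) from sudden deaths with few
# accompanying conditions (small scale): it multiplies both the shared
# background (cardiac arrest, ill-defined causes) and the cluster's own
# comorbidity profile.
_BENCHMARK_CLUSTERS: list[tuple] = [
    ("other_cardiovascular", 0.100, ("heart_failure", "hypertensive_heart_disease"), (0.99, 0.80), 2.45, 79, 12, {}),
    ("ischemic_heart", 0.115, ("atherosclerotic_heart_disease", "myocardial_infarction"), (0.99, 0.30), 0.55, 75, 13, {}),
    ("other_cancer", 0.115, ("other_cancer", "breast_cancer"), (0.99, 0.30), 0.55, 67, 14,
     {"marital": {"married": 0.50, "widowed": 0.24, "divorced": 0.14, "never_married": 0.12},
      "education": {"primary": 0.09, "secondary": 0.51, "tertiary": 0.40},
      "place": {"hospital_inpatient": 0.24, "hospital_outpatient_er": 0.03, "hospital_doa": 0.004,
                "home": 0.40, "hospice": 0.12, "nursing_home": 0.146, "other": 0.06}}),
    ("urological_gi_infection", 0.095, ("other_sepsis", "unspecified_kidney_failure"), (0.99, 0.80), 2.45, 76, 13,
     {"place": {"hospital_inpatient": 0.58, "hospital_outpatient_er": 0.06, "hospital_doa": 0.004,
                "home": 0.12, "hospice": 0.04, "nursing_home": 0.146, "other": 0.05}}),
    ("respiratory", 0.085, ("copd", "respiratory_failure"), (0.99, 0.80), 2.45, 74, 11,
     {"education": {"primary": 0.16, "secondary": 0.60, "tertiary": 0.24}}),
    ("stroke", 0.075, ("unspecified_stroke", "hypertension"), (0.99, 0.30), 0.55, 79, 12, {}),
    ("geriatric", 0.060, ("dementia", "pneumonitis"), (0.99, 0.80), 2.45, 85, 8,
     {"sex": {"female": 0.62, "male": 0.38},
      "marital": {"married": 0.17, "widowed": 0.58, "divorced": 0.12, "never_married": 0.13},
      "place": {"hospital_inpatient": 0.17, "hospital_outpatient_er": 0.03, "hospital_doa": 0.004,
                "home": 0.15, "hospice": 0.05, "nursing_home": 0.504, "other": 0.092}}),
    ("lung_cancer", 0.060, ("lung_cancer", "nicotine_dependence"), (0.99, 0.30), 0.55, 70, 11,
     {"marital": {"married": 0.49, "widowed": 0.25, "divorced": 0.15, "never_married": 0.11}}),
    ("neurodegenerative", 0.045, ("alzheimer_disease", "parkinson_disease"), (0.99, 0.80), 2.45, 84, 8,
     {"sex": {"female": 0.58, "male": 0.42}}),
    ("diabetes_metabolic", 0.040, ("diabetes_mellitus", "obesity"), (0.99, 0.80), 2.45, 70, 13, {}),
    ("gastrointestinal_cancer", 0.040, ("gastrointestinal_cancer", "colorectal_cancer"), (0.99, 0.80), 2.45, 71, 12,
     {"marital": {"married": 0.49, "widowed": 0.25, "divorced": 0.14, "never_married": 0.12}}),
    ("chronic_kidney", 0.035, ("chronic_kidney_disease", "urinary_tract_infection"), (0.99, 0.80), 2.45, 78, 12, {}),
    ("hematologic_cancer", 0.030, ("non_hodgkin_lymphoma", "prostate_cancer"), (0.99, 0.80), 2.45, 73, 13, {}),
    ("liver", 0.030, ("alcoholic_liver_disease", "liver_fibrosis_cirrhosis"), (0.99, 0.80), 2.45, 58, 12,
     {"sex": {"female": 0.36, "male": 0.64}}),
    ("poisoning", 0.040, ("drug_poisoning", "alcohol_poisoning"), (0.99, 0.30), 0.17, 42, 14,
     {"marital": {"married": 0.25, "widowed": 0.05, "divorced": 0.25, "never_married": 0.45},
      "manner": _EXTERNAL_MANNER,
      "place": {"hospital_inpatient": 0.18, "hospital_outpatient_er": 0.20, "hospital_doa": 0.03,
                "home": 0.42, "hospice": 0.004, "nursing_home": 0.016, "other": 0.15}}),
    ("open_wound_suffocation", 0.035, ("open_wound", "suffocation"), (0.99, 0.30), 0.17, 44, 16,
     {"sex": {"female": 0.24, "male": 0.76},
      "marital": {"married": 0.27, "widowed": 0.06, "divorced": 0.21, "never_married": 0.46},
      "manner": _EXTERNAL_MANNER,
      "place": {"hospital_inpatient": 0.20, "hospital_outpatient_er": 0.22, "hospital_doa": 0.04,
                "home": 0.30, "hospice": 0.004, "nursing_home": 0.016, "other": 0.22}}),
]

# Background structure before per-cluster scaling. Cardiac arrest and the
# fallback bucket are common on certificates regardless of cluster; beyond
# those, each cluster carries its own comorbidity profile: a window of
# _BG_PROFILE_SIZE categories at elevated prevalence (rolled through the
# vocabulary so profiles differ between clusters) over a thin floor.
_BG_SHARED = {"cardiac_arrest": 0.115, "other": 0.105}
_BG_PROFILE_HIGH = 0.124
_BG_PROFILE_FLOOR = 0.0026
_BG_PROFILE_SIZE = 5
_BG_PROFILE_STEP = 7
_BACKGROUND_CAP = 0.45

#: Default attribute missingness, matching the share of records with an
#: unknown level implied by the published whole-population margins
#: (education ~3.3%, marital ~1.0%, place ~0.5%, manner ~19.1%).
DEFAULT_MISSINGNESS = {
    "education": 0.0331,
    "marital": 0.0103,
    "place_of_death": 0.0050,
    "manner": 0.1907,
}


def default_benchmark_spec(n_records: int = 100_000, seed: int = 0) -> PopulationSpec:
    """The 16-cluster benchmark population over the demo vocabulary.

    Each cluster owns a disjoint pair of signature categories — the first
    at prevalence 0.99 so the cluster's defining condition is near-certain
    on the certificate, the second at 0.80 in the chronic clusters and
    0.30 in the sudden-death ones — plus a scaled shared background and a
    cluster-specific comorbidity profile. The clusters are deliberately
    well separated (disjoint high-prevalence category sets); weights,
    background scales and age parameters are calibrated so a draw of
    100,000 records reproduces the real data's gross margins: mean
    conditions per record near 3.0, multimorbidity near 78%, mean age at
    death near 73 years.
    """
    cmap = demo_category_map()
    vocab = cmap.category_vocabulary
    codes = representative_codes(cmap)
    col = {label: j for j, label in enumerate(vocab)}

    shared_idx = [col[l] for l in _BG_SHARED]
    profile_pool = [j for j in range(len(vocab)) if j not in shared_idx]

    clusters: list[ClusterSpec] = []
    for ci, (label, weight, sigs, sig_p, bg_scale, age_mean, age_sd, over) in enumerate(
        _BENCHMARK_CLUSTERS
    ):
        prev = np.full(len(vocab), _BG_PROFILE_FLOOR * bg_scale)
        for l, p in _BG_SHARED.items():
            prev[col[l]] = p * bg_scale
        for j in range(_BG_PROFILE_SIZE):
            pos = profile_pool[(ci * _BG_PROFILE_STEP + j) % len(profile_pool)]
            prev[pos] = _BG_PROFILE_HIGH * bg_scale
        prev = np.minimum(prev, _BACKGROUND_CAP)
        for s, p in zip(sigs, sig_p):
            prev[col[s]] = p
        uw = prev.copy()
        for s in sigs:
            uw[col[s]] *= 5.0  # the signature disease drives the underlying cause
        clusters.append(
            ClusterSpec(
                label=label,
                weight=weight,
                condition_prevalence=prev,
                age_mean=age_mean,
                age_sd=age_sd,
                sex_probs=over.get("sex", _BASE["sex"]),
                race_probs=over.get("race", _BASE["race"]),
                education_probs=over.get("education", _BASE["education"]),
                marital_probs=over.get("marital", _BASE["marital"]),
                place_probs=over.get("place", _BASE["place"]),
                manner_probs=over.get("manner", _BASE["manner"]),
                underlying_weights=uw,
            )
        )
    spec = PopulationSpec(
        n_records=n_records,
        vocabulary=vocab,
        clusters=clusters,
        codes=codes,
        missingness=dict(DEFAULT_MISSINGNESS),
        seed=seed,
    )
    spec.validate()
    return spec


def write_records_csv(records: Sequence[RawDeathRecord], path: str | Path) -> None:
    """Write records in the delimited schema the ingest stage reads
    (conditions space-delimited in one field; missing values empty)."""
    fields = [
        "record_id", "data_year", "age_years", "sex", "race", "education",
        "marital", "resident_status", "place_of_death", "manner",
        "underlying_cause", "conditions",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(fields)
        for r in records:
            w.writerow(
                [
                    r.record_id,
                    r.data_year,
                    "" if r.age_years is None else r.age_years,
                    r.sex,
                    r.race,
                    r.education or "",
                    r.marital or "",
                    r.resident_status,
                    r.place_of_death or "",
                    r.manner or "",
                    r.underlying_cause,
                    " ".join(r.entity_conditions),
                ]
            )


def write_labels_csv(
    records: Sequence[RawDeathRecord], latent: np.ndarray, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "latent_cluster"])
        for r, lab in zip(records, latent):
            w.writerow([r.record_id, int(lab)])
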