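"""Synthetic spontaneous-report database with planted drug–reaction signals.

Real pharmacovigilance databases are access-restricted, so simulation
studies (null calibration, signal recovery) run on generated Individual
Case Safety Reports whose statistical structure matches what the
case/non-case analysis assumes:

* an age-band mix over infants, children, adolescents and adults, with ages
  drawn uniformly in months within each band and recorded in the unit a
  notifier would use (days under 2 months, months under 2 years, years
  otherwise) to exercise unit normalization downstream;
* age-band-dependent drug exposure — vaccines dominate infancy,
  immunosuppressants and steroids childhood, psychotropics adolescence —
  with the number of drugs per report drawn as ``1 + Poisson(mean)`` and the
  drugs themselves sampled without replacement with probability
  proportional to the band's exposure weights (Gumbel top-k);
* independent per-PT reaction reporting at baseline probability ``p0``,
  multiplied by the rate ratio ``lambda`` of every planted association whose
  drug is present on the report and whose band matches (capped at 1).  Since
  baseline probabilities are small, the case/non-case odds ratio for a
  planted pair is approximately ``lambda``, which is what makes recovery
  simulations interpretable;
* a guaranteed-reaction rule — a report on which no PT fired receives one PT
  drawn proportional to that report's PT probabilities — because a
  spontaneous report without a reaction does not exist.  This slightly
  inflates low-probability PTs, so null behaviour is asserted empirically by
  simulation rather than analytically.

Generation is vectorized and fully reproducible: one seed, one dataset,
with all randomness drawn from a single ``numpy`` generator in a fixed
phase order (bands, ages, demographics, drug counts, drug selection, roles,
reactions, fallback reactions, seriousness criteria).

Alongside the reports a :class:`GroundTruth` is emitted holding the planted
associations and the realized per-band margins (per-drug, per-PT and
per-pair counts, drug roles restricted to suspect/interacting), which
recovery tests use as an independent bookkeeping oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .icsr import DrugEntry, IcsrReport, ReportSet, canonicalize

BandName = Literal["infant", "child", "adolescent", "adult"]
BAND_ORDER: tuple[str, ...] = ("infant", "child", "adolescent", "adult")

#: Half-open age bounds in months per generator band.  The adult band is a
#: background population (18 to 86 years).
AGE_BOUNDS_MONTHS: dict[str, tuple[float, float]] = {
    "infant": (0.0, 24.0),
    "child": (24.0, 144.0),
    "adolescent": (144.0, 216.0),
    "adult": (216.0, 1032.0),
}

_SERIOUSNESS_CRITERIA = (
    "hospitalization",
    "other_medically_important",
    "life_threatening",
    "disability",
    "congenital_anomaly",
)
_SERIOUSNESS_WEIGHTS = (0.60, 0.25, 0.08, 0.05, 0.02)

_MIX_TOL = 1e-9


class PlantedAssociation(BaseModel):
    """A drug–PT pair whose reporting rate is multiplied by ``rate_ratio``.

    ``age_band="all"`` applies the multiplier in every band.  The rate ratio
    plays the role the ROR estimates: the factor by which the reaction is
    more frequently reported when the drug is on the report.
    """

    model_config = ConfigDict(frozen=True)

    drug_name: str
    pt: str
    age_band: Literal["infant", "child", "adolescent", "adult", "all"] = "all"
    rate_ratio: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _canon(self) -> "PlantedAssociation":
        object.__setattr__(self, "drug_name", canonicalize(self.drug_name))
        object.__setattr__(self, "pt", canonicalize(self.pt))
        if not math.isfinite(self.rate_ratio):
            raise ValueError("rate_ratio must be finite")
        return self


class GeneratorConfig(BaseModel):
    """Simulation parameters for one synthetic report database."""

    n_reports: int = Field(ge=1)
    seed: int = 0
    age_band_mix: dict[BandName, float]
    drug_catalog: dict[str, dict[BandName, float]]
    drugs_per_report_poisson_mean: float = Field(default=0.7, ge=0.0)
    pt_catalog: dict[str, float]
    pts_per_report_min: int = Field(default=1, ge=1)
    planted: list[PlantedAssociation] = Field(default_factory=list)
    sex_mix: dict[str, float]
    country_mix: dict[str, float]
    reporter_mix: dict[str, float]
    p_serious: float = Field(ge=0.0, le=1.0)
    outcome_mix: dict[str, float]
    suspect_role_prob: float = Field(default=0.8, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        problems: list[str] = []
        self.drug_catalog = {
            canonicalize(k): dict(v) for k, v in self.drug_catalog.items()
        }
        self.pt_catalog = {canonicalize(k): v for k, v in self.pt_catalog.items()}
        for label, mix in (
            ("age_band_mix", self.age_band_mix),
            ("sex_mix", self.sex_mix),
            ("country_mix", self.country_mix),
            ("reporter_mix", self.reporter_mix),
            ("outcome_mix", self.outcome_mix),
        ):
            if any(p < 0 or p > 1 for p in mix.values()):
                problems.append(f"{label}: probabilities must lie in [0, 1]")
            if abs(sum(mix.values()) - 1.0) > _MIX_TOL:
                problems.append(f"{label}: probabilities must sum to 1")
        for drug, probs in self.drug_catalog.items():
            if any(p < 0 or p > 1 for p in probs.values()):
                problems.append(f"drug_catalog[{drug}]: probabilities must lie in [0, 1]")
        for pt, p0 in self.pt_catalog.items():
            if p0 < 0 or p0 > 1:
                problems.append(f"pt_catalog[{pt}]: probability must lie in [0, 1]")
        if sum(self.pt_catalog.values()) <= 0:
            problems.append("pt_catalog: at least one PT needs positive probability")
        if self.pts_per_report_min > len(self.pt_catalog):
            problems.append("pts_per_report_min: exceeds the number of catalogued PTs")
        for band, share in self.age_band_mix.items():
            if share > 0 and not any(
                probs.get(band, 0.0) > 0 for probs in self.drug_catalog.values()
            ):
                problems.append(
                    f"drug_catalog: no drug has positive exposure in band '{band}'"
                )
        for pa in self.planted:
            if pa.drug_name not in self.drug_catalog:
                problems.append(f"planted: drug '{pa.drug_name}' not in drug_catalog")
            if pa.pt not in self.pt_catalog:
                problems.append(f"planted: PT '{pa.pt}' not in pt_catalog")
        if problems:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(problems))
        return self


@dataclass
class BandMargins:
    """Realized counts within one generator band (roles: suspect/interacting)."""

    n_reports: int
    drug_counts: dict[str, int] = field(default_factory=dict)
    pt_counts: dict[str, int] = field(default_factory=dict)
    pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Planted associations plus realized margins of the emitted set."""

    planted: list[PlantedAssociation]
    margins: dict[str, BandMargins]


_REPORT_FIELD_NAMES = frozenset(IcsrReport.model_fields)


def _fast_report(data: dict) -> IcsrReport:
    """Construct a report without validation (generator-internal fast path).

    Semantically equivalent to ``IcsrReport.model_construct`` with every
    field supplied; the generator guarantees schema-valid, pre-canonicalized
    values.
    """
    r = IcsrReport.__new__(IcsrReport)
    object.__setattr__(r, "__dict__", data)
    object.__setattr__(r, "__pydantic_fields_set__", set(_REPORT_FIELD_NAMES))
    object.__setattr__(r, "__pydantic_extra__", None)
    object.__setattr__(r, "__pydantic_private__", None)
    return r


def _choice(rng: np.random.Generator, mix: dict[str, float], n: int) -> np.ndarray:
    cats = list(mix.keys())
    p = np.asarray(list(mix.values()), dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(cats), size=n, p=p)
    return np.asarray(cats, dtype=object)[idx]


def generate_report_set(cfg: GeneratorConfig) -> tuple[ReportSet, GroundTruth]:
    """Generate exactly ``cfg.n_reports`` reports plus their ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    drugs = list(cfg.drug_catalog.keys())
    pts = list(cfg.pt_catalog.keys())
    n_drugs, n_pts = len(drugs), len(pts)
    drug_index = {d: i for i, d in enumerate(drugs)}
    pt_index = {p: j for j, p in enumerate(pts)}
    band_labels = [b for b in BAND_ORDER if cfg.age_band_mix.get(b, 0.0) > 0]

    # phase 1: bands and ages (uniform in months within the band)
    band_p = np.asarray([cfg.age_band_mix[b] for b in band_labels])
    band_idx = rng.choice(len(band_labels), size=n, p=band_p / band_p.sum())
    lo = np.asarray([AGE_BOUNDS_MONTHS[b][0] for b in band_labels])[band_idx]
    hi = np.asarray([AGE_BOUNDS_MONTHS[b][1] for b in band_labels])[band_idx]
    months = lo + rng.random(n) * (hi - lo)

    # phase 2: demographics
    sex = _choice(rng, cfg.sex_mix, n)
    country = _choice(rng, cfg.country_mix, n)
    reporter = _choice(rng, cfg.reporter_mix, n)
    outcome = _choice(rng, cfg.outcome_mix, n)
    serious = rng.random(n) < cfg.p_serious
    fatal = outcome == "fatal"
    serious |= fatal  # a fatal outcome is serious by definition
    crit_idx = rng.choice(
        len(_SERIOUSNESS_CRITERIA), size=n, p=np.asarray(_SERIOUSNESS_WEIGHTS)
    )

    # phase 3: drug selection — weighted sampling without replacement via
    # Gumbel top-k on the band's exposure weights
    weights = np.zeros((len(band_labels), n_drugs))
    for bi, b in enumerate(band_labels):
        for d, probs in cfg.drug_catalog.items():
            weights[bi, drug_index[d]] = probs.get(b, 0.0)
    w = weights[band_idx]  # (n, n_drugs)
    k = 1 + rng.poisson(cfg.drugs_per_report_poisson_mean, size=n)
    nnz = (w > 0).sum(axis=1)
    k = np.minimum(k, nnz)
    with np.errstate(divide="ignore"):
        score = np.where(w > 0, np.log(w), -np.inf) + rng.gumbel(size=(n, n_drugs))
    order = np.argsort(-score, axis=1)
    kmax = int(k.max())
    pos_mask = np.arange(kmax)[None, :] < k[:, None]
    sel_rows = np.repeat(np.arange(n), k)
    sel_cols = order[:, :kmax][pos_mask]
    presence = np.zeros((n, n_drugs), dtype=bool)
    presence[sel_rows, sel_cols] = True

    # phase 4: roles (planted-association drugs are always suspect)
    suspect = rng.random((n, n_drugs)) < cfg.suspect_role_prob
    planted_cols = {drug_index[pa.drug_name] for pa in cfg.planted}
    for col in planted_cols:
        suspect[:, col] = True

    # phase 5: reactions
    band_arr = np.asarray(band_labels, dtype=object)[band_idx]
    probs = np.tile(np.asarray([cfg.pt_catalog[p] for p in pts]), (n, 1))
    for pa in cfg.planted:
        col = drug_index[pa.drug_name]
        mask = presence[:, col]
        if pa.age_band != "all":
            mask = mask & (band_arr == pa.age_band)
        probs[mask, pt_index[pa.pt]] *= pa.rate_ratio
    np.clip(probs, 0.0, 1.0, out=probs)
    fires = rng.random((n, n_pts)) < probs

    # guaranteed-reaction rule: top up reports below the PT minimum, one PT
    # at a time, drawn proportional to the report's remaining PT probabilities
    for _ in range(cfg.pts_per_report_min):
        short = np.flatnonzero(fires.sum(axis=1) < cfg.pts_per_report_min)
        if short.size == 0:
            break
        p_rows = np.where(fires[short], 0.0, probs[short])
        totals = p_rows.sum(axis=1)
        # degenerate rows (all remaining probs zero) fall back to uniform
        uniform = np.where(fires[short], 0.0, 1.0)
        p_rows = np.where(totals[:, None] > 0, p_rows, uniform)
        totals = p_rows.sum(axis=1)
        u = rng.random(short.size) * totals
        chosen = (np.cumsum(p_rows, axis=1) < u[:, None]).sum(axis=1)
        fires[short, np.minimum(chosen, n_pts - 1)] = True

    # assemble reports (trusted fast path: fields are schema-valid by design;
    # round-trip tests assert equivalence with validated construction)
    rows_d, cols_d = np.nonzero(presence)
    sus_flags = suspect[rows_d, cols_d].tolist()
    ptr_d = np.concatenate(([0], np.cumsum(np.bincount(rows_d, minlength=n)))).tolist()
    cols_d_l = cols_d.tolist()
    rows_p, cols_p = np.nonzero(fires)
    ptr_p = np.concatenate(([0], np.cumsum(np.bincount(rows_p, minlength=n)))).tolist()
    cols_p_l = cols_p.tolist()

    entry_cache = {
        (c, s): DrugEntry(drug_name=drugs[c], role="suspect" if s else "concomitant")
        for c in range(n_drugs)
        for s in (True, False)
    }
    singleton_pt = [frozenset({p}) for p in pts]
    crit_plain = [frozenset({c}) for c in _SERIOUSNESS_CRITERIA]
    crit_fatal = [frozenset({c, "death"}) for c in _SERIOUSNESS_CRITERIA]
    no_criteria = frozenset()

    months_l = months.tolist()
    sex_l, country_l, reporter_l, outcome_l = (
        sex.tolist(), country.tolist(), reporter.tolist(), outcome.tolist(),
    )
    serious_l, fatal_l, crit_idx_l = serious.tolist(), fatal.tolist(), crit_idx.tolist()

    width = max(7, len(str(n)))
    reports: list[IcsrReport] = []
    for i in range(n):
        m = months_l[i]
        if m < 2.0:
            unit, value = "days", m * 30.4375
        elif m < 24.0:
            unit, value = "months", m
        else:
            unit, value = "years", m / 12.0
        entries = [
            entry_cache[(cols_d_l[j], sus_flags[j])]
            for j in range(ptr_d[i], ptr_d[i + 1])
        ]
        lo, hi_p = ptr_p[i], ptr_p[i + 1]
        if hi_p - lo == 1:
            reactions = singleton_pt[cols_p_l[lo]]
        else:
            reactions = frozenset(pts[j] for j in cols_p_l[lo:hi_p])
        if serious_l[i]:
            criteria = (
                crit_fatal[crit_idx_l[i]] if fatal_l[i] else crit_plain[crit_idx_l[i]]
            )
        else:
            criteria = no_criteria
        reports.append(
            _fast_report(
                {
                    "report_id": f"R{i + 1:0{width}d}",
                    "age_value": value,
                    "age_unit": unit,
                    "sex": sex_l[i],
                    "country": country_l[i],
                    "reporter_qualification": reporter_l[i],
                    "drugs": entries,
                    "reactions": reactions,
                    "serious": serious_l[i],
                    "seriousness_criteria": criteria,
                    "outcome": outcome_l[i],
                }
            )
        )

    # realized margins per band, drug roles restricted to suspect/interacting
    case_presence = presence & suspect
    margins: dict[str, BandMargins] = {}
    for bi, b in enumerate(band_labels):
        mask = band_idx == bi
        pres_b = case_presence[mask]
        fires_b = fires[mask]
        pair = pres_b.T.astype(np.int64) @ fires_b.astype(np.int64)
        bm = BandMargins(n_reports=int(mask.sum()))
        d_counts = pres_b.sum(axis=0)
        p_counts = fires_b.sum(axis=0)
        bm.drug_counts = {
            drugs[i]: int(c) for i, c in enumerate(d_counts) if c > 0
        }
        bm.pt_counts = {pts[j]: int(c) for j, c in enumerate(p_counts) if c > 0}
        nz_i, nz_j = np.nonzero(pair)
        bm.pair_counts = {
            (drugs[i], pts[j]): int(pair[i, j]) for i, j in zip(nz_i, nz_j)
        }
        margins[b] = bm

    rs = ReportSet(
        reports=reports,
        provenance=f"synthetic(seed={cfg.seed}, n={n})",
    )
    return rs, GroundTruth(planted=list(cfg.planted), margins=margins)


def with_rate_ratios_nulled(cfg: GeneratorConfig) -> GeneratorConfig:
    """Copy of a config with every planted rate ratio forced to 1 (null)."""
    planted = [pa.model_copy(update={"rate_ratio": 1.0}) for pa in cfg.planted]
    return cfg.model_copy(update={"planted": planted})


def default_pediatric_config(scale: int = 1, seed: int = 0) -> GeneratorConfig:
    """Default simulated database emulating a pediatric safety-report mix.

    ``scale=1`` yields 50,000 reports.  Exposure weights give vaccines high
    exposure in infants, immunosuppressants and corticosteroids in children
    and antipsychotics/psychotropics in adolescents, over a larger adult
    background.  The PT catalog contains the catatonia family (catatonia,
    malignant and withdrawal catatonia, posturing, echolalia, echopraxia,
    automatism, waxy flexibility) at low baseline rates next to common
    background reactions.  The planted associations mirror the qualitative
    signal structure of published pediatric catatonia screens: vaccine–
    posturing/echolalia signals in infancy, immunosuppressant/steroid and
    antipsychotic signals in childhood, antipsychotic and benzodiazepine
    signals in adolescence.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")

    def bands(infant=0.0, child=0.0, adolescent=0.0, adult=0.0):
        return {
            "infant": infant,
            "child": child,
            "adolescent": adolescent,
            "adult": adult,
        }

    drug_catalog = {
        "pneumococcal vaccine": bands(0.30, 0.02, 0.005, 0.002),
        "dtp vaccine": bands(0.28, 0.03, 0.01, 0.002),
        "mmr vaccine": bands(0.22, 0.04, 0.005, 0.001),
        "hepatitis b vaccine": bands(0.18, 0.02, 0.01, 0.005),
        "rotavirus vaccine": bands(0.15, 0.002, 0.0, 0.0),
        "hpv vaccine": bands(0.0, 0.03, 0.06, 0.005),
        "meningococcal vaccine": bands(0.02, 0.03, 0.04, 0.002),
        "influenza vaccine": bands(0.05, 0.05, 0.04, 0.05),
        "ciclosporin": bands(0.005, 0.04, 0.02, 0.02),
        "prednisolone": bands(0.01, 0.05, 0.03, 0.04),
        "methylprednisolone": bands(0.005, 0.03, 0.02, 0.03),
        "risperidone": bands(0.001, 0.03, 0.07, 0.02),
        "olanzapine": bands(0.0, 0.01, 0.06, 0.03),
        "quetiapine": bands(0.0, 0.008, 0.04, 0.03),
        "aripiprazole": bands(0.0, 0.008, 0.03, 0.02),
        "haloperidol": bands(0.001, 0.01, 0.03, 0.02),
        "chlorpromazine": bands(0.0, 0.005, 0.02, 0.01),
        "lorazepam": bands(0.002, 0.01, 0.04, 0.04),
        "valproic acid": bands(0.005, 0.03, 0.04, 0.02),
        "fluoxetine": bands(0.0, 0.01, 0.05, 0.04),
        "sertraline": bands(0.0, 0.008, 0.04, 0.04),
        "methylphenidate": bands(0.0, 0.05, 0.05, 0.01),
        "ondansetron": bands(0.01, 0.03, 0.02, 0.03),
        "midazolam": bands(0.02, 0.02, 0.02, 0.02),
        "amoxicillin": bands(0.10, 0.10, 0.05, 0.05),
        "paracetamol": bands(0.10, 0.10, 0.10, 0.12),
        "ibuprofen": bands(0.05, 0.08, 0.10, 0.10),
        "metformin": bands(0.0, 0.0, 0.01, 0.08),
        "atorvastatin": bands(0.0, 0.0, 0.0, 0.08),
        "lisinopril": bands(0.0, 0.0, 0.0, 0.07),
    }

    pt_catalog = {
        "catatonia": 0.003,
        "posturing": 0.004,
        "echolalia": 0.002,
        "echopraxia": 0.001,
        "automatism": 0.0015,
        "waxy flexibility": 0.001,
        "malignant catatonia": 0.0008,
        "withdrawal catatonia": 0.0005,
        "neuroleptic malignant syndrome": 0.002,
        "unresponsive to stimuli": 0.008,
        "speech disorder": 0.006,
        "stereotypy": 0.002,
        "eating disorder": 0.003,
        "social avoidant behaviour": 0.001,
        "agitation": 0.04,
        "seizure": 0.025,
        "pyrexia": 0.08,
        "insomnia": 0.04,
        "drug ineffective": 0.06,
        "nausea": 0.07,
        "headache": 0.07,
        "rash": 0.06,
        "vomiting": 0.06,
        "somnolence": 0.04,
        "dizziness": 0.05,
    }

    planted = [
        # infancy: vaccine-dominated catatonia-family reporting
        PlantedAssociation(drug_name="pneumococcal vaccine", pt="catatonia", age_band="infant", rate_ratio=6.0),
        PlantedAssociation(drug_name="dtp vaccine", pt="posturing", age_band="infant", rate_ratio=6.0),
        PlantedAssociation(drug_name="pneumococcal vaccine", pt="posturing", age_band="infant", rate_ratio=6.0),
        PlantedAssociation(drug_name="mmr vaccine", pt="echolalia", age_band="infant", rate_ratio=7.0),
        PlantedAssociation(drug_name="valproic acid", pt="echolalia", age_band="infant", rate_ratio=25.0),
        # childhood: immunosuppressant / steroid / antipsychotic signals
        PlantedAssociation(drug_name="ciclosporin", pt="catatonia", age_band="child", rate_ratio=12.0),
        PlantedAssociation(drug_name="prednisolone", pt="catatonia", age_band="child", rate_ratio=10.0),
        PlantedAssociation(drug_name="haloperidol", pt="catatonia", age_band="child", rate_ratio=30.0),
        PlantedAssociation(drug_name="ondansetron", pt="catatonia", age_band="child", rate_ratio=15.0),
        PlantedAssociation(drug_name="hpv vaccine", pt="posturing", age_band="child", rate_ratio=8.0),
        # adolescence: psychotropic signals
        PlantedAssociation(drug_name="olanzapine", pt="catatonia", age_band="adolescent", rate_ratio=25.0),
        PlantedAssociation(drug_name="risperidone", pt="catatonia", age_band="adolescent", rate_ratio=15.0),
        PlantedAssociation(drug_name="quetiapine", pt="catatonia", age_band="adolescent", rate_ratio=15.0),
        PlantedAssociation(drug_name="haloperidol", pt="catatonia", age_band="adolescent", rate_ratio=20.0),
        PlantedAssociation(drug_name="chlorpromazine", pt="catatonia", age_band="adolescent", rate_ratio=35.0),
        PlantedAssociation(drug_name="lorazepam", pt="catatonia", age_band="adolescent", rate_ratio=18.0),
        PlantedAssociation(drug_name="olanzapine", pt="withdrawal catatonia", age_band="adolescent", rate_ratio=25.0),
        PlantedAssociation(drug_name="lorazepam", pt="withdrawal catatonia", age_band="adolescent", rate_ratio=25.0),
        PlantedAssociation(drug_name="risperidone", pt="malignant catatonia", age_band="adolescent", rate_ratio=15.0),
        PlantedAssociation(drug_name="olanzapine", pt="echolalia", age_band="adolescent", rate_ratio=20.0),
    ]

    return GeneratorConfig(
        n_reports=50_000 * scale,
        seed=seed,
        age_band_mix={"infant": 0.08, "child": 0.17, "adolescent": 0.25, "adult": 0.50},
        drug_catalog=drug_catalog,
        pt_catalog=pt_catalog,
        planted=planted,
        sex_mix={"female": 0.47, "male": 0.51, "unknown": 0.02},
        country_mix={
            "US": 0.55,
            "CA": 0.04,
            "GB": 0.05,
            "DE": 0.05,
            "FR": 0.05,
            "IT": 0.03,
            "CN": 0.03,
            "AU": 0.03,
            "JP": 0.03,
            "unknown": 0.14,
        },
        reporter_mix={
            "physician": 0.35,
            "pharmacist": 0.03,
            "other_health_professional": 0.15,
            "lawyer": 0.005,
            "consumer": 0.145,
            "unknown": 0.32,
        },
        p_serious=0.45,
        outcome_mix={
            "unknown": 0.70,
            "recovered": 0.16,
            "recovering": 0.07,
            "not_recovered": 0.04,
            "recovered_with_sequelae": 0.015,
            "fatal": 0.015,
        },
    )


def config_from_yaml(path) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML file mirroring its fields."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return GeneratorConfig.model_validate(raw)


def config_to_yaml(cfg: GeneratorConfig, path) -> None:
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
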