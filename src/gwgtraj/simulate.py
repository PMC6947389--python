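"""Seeded synthetic perinatal cohorts with latent weight-gain trajectory groups.

The generator emulates the structure a trimester-resolved gestational
weight-gain (GWG) analysis needs, without any real patient data:

* three latent trajectory groups with configurable shares (default 58.3 /
  32.4 / 9.3 %) whose pre-pregnancy BMI distributions centre at 21.2, 26.3
  and 35.6 kg/m^2 — a mostly-normal-weight group, a mostly-overweight group
  that gains the most, and a mostly-obese group;
* absolute maternal weight over gestation: the pre-pregnancy weight anchors
  the curve at week 0 and a group-specific polynomial mean gain accumulates
  over the weeks, scaled by a per-woman frailty factor and observed with
  per-visit measurement noise at one weighing per trimester;
* seven binary outcomes.  GDM, hypertensive disorders, caesarean delivery
  and neonatal hypoglycemia are Bernoulli draws from log-linear risk models
  (risk = exp(b0 + sum b_k x_k)), so the generating relative risks are known
  exactly.  SGA and LGA are drawn jointly the same way and the birth weight
  is then sampled *consistently* from the tails/centre of a Normal
  reference distribution linear in gestational age at delivery; macrosomia
  is always derived as birth weight strictly above 4000 g.

Risk models may reference covariates and the IOM compliance labels computed
from the simulated weights, which makes confounded exposure-outcome
structures (and hence adjusted-RR recovery experiments) possible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import iom

__all__ = [
    "OutcomeModel",
    "BirthweightReference",
    "SimulationConfig",
    "CohortRecord",
    "generate_cohort",
    "assign_outcomes",
    "cohort_to_long",
    "default_config",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Outcomes drawn from log-linear Bernoulli models.
MODELLED_OUTCOMES = ("gdm", "hdp", "caesarean", "sga", "lga", "hypoglycemia")
#: All outcome columns (macrosomia derived from birth weight, never modelled).
OUTCOMES = ("gdm", "hdp", "caesarean", "macrosomia", "sga", "lga", "hypoglycemia")

MACROSOMIA_CUTOFF_G = 4000.0  # macrosomia = birth weight strictly above this

COVARIATES = (
    "age",
    "parity",
    "smoking",
    "chronic_hypertension",
    "prior_diabetes",
    "diploma",
    "low_income",
)


@dataclass(frozen=True)
class OutcomeModel:
    """Log-linear risk model: P(event) = exp(intercept + sum coef * feature).

    ``intercept`` is the log baseline risk at feature values 0; coefficient
    keys name feature columns (covariates, ``age_c`` = age - 30, or exposure
    dummies such as ``iom_t3_H``) and values are log relative risks.
    """

    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)

    def risk(self, features: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(features), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            if name not in features.columns:
                raise ValueError(f"outcome model references missing covariate {name!r}")
            eta += coef * features[name].to_numpy(dtype=float)
        p = np.exp(eta)
        if np.any(p > 1.0):
            warnings.warn(
                f"{int(np.sum(p > 1.0))} risks exceeded 1 and were clipped",
                RuntimeWarning,
                stacklevel=2,
            )
        return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class BirthweightReference:
    """Normal birth-weight reference, mean linear in gestational age at delivery."""

    mean_at_40: float = 3400.0  # g
    slope_per_week: float = 180.0  # g per gestational week
    sd: float = 450.0  # g

    def mean(self, ga_delivery: np.ndarray) -> np.ndarray:
        return self.mean_at_40 + self.slope_per_week * (np.asarray(ga_delivery) - 40.0)

    def percentile(self, q: float, ga_delivery: np.ndarray) -> np.ndarray:
        return self.mean(ga_delivery) + self.sd * sps.norm.ppf(q)


# Mean-gain shape: fraction of the week-34 gain accumulated by week g,
# f(g) = a*g + b*g^2 with f(34) = 1 and f(22) ~ 0.54 (gain accelerates after
# the first trimester).
_SHAPE_A = 0.0152375
_SHAPE_B = 4.16890e-4


def _gain_curve(total_at_34: float) -> tuple[float, float, float]:
    """Polynomial (c0, c1, c2) for mean gain reaching ``total_at_34`` kg at week 34."""
    return (0.0, total_at_34 * _SHAPE_A, total_at_34 * _SHAPE_B)


def _default_outcome_models() -> dict[str, OutcomeModel]:
    """Generating risk models, exposure = third-trimester IOM label (ref N).

    Baseline risks follow the reference-level event rates of a large
    North-American pregnancy cohort and the exposure log-RRs are set to that
    cohort's covariate-adjusted estimates, so the true conditional relative
    risks of the simulation are known round numbers (e.g. 2.26 for LGA under
    third-trimester gain above guidelines).
    """
    ln = np.log
    return {
        "gdm": OutcomeModel(ln(0.061), {
            "iom_t3_L": ln(1.69), "iom_t3_H": ln(1.11),
            "age_c": 0.03, "parity": 0.05, "smoking": 0.10,
            "chronic_hypertension": 0.30, "diploma": -0.15, "low_income": 0.20,
        }),
        "hdp": OutcomeModel(ln(0.029), {
            "iom_t3_L": ln(0.82), "iom_t3_H": ln(1.91),
            "age_c": 0.02, "parity": -0.10, "smoking": -0.30,
            "chronic_hypertension": 1.60, "prior_diabetes": 0.50,
            "diploma": -0.10, "low_income": 0.10,
        }),
        "caesarean": OutcomeModel(ln(0.176), {
            "iom_t3_L": ln(1.11), "iom_t3_H": ln(1.34),
            "age_c": 0.03, "parity": -0.15, "smoking": 0.05,
            "chronic_hypertension": 0.30, "prior_diabetes": 0.40, "low_income": 0.10,
        }),
        "sga": OutcomeModel(ln(0.065), {
            "iom_t3_L": ln(1.48), "iom_t3_H": ln(0.58),
            "smoking": 0.50, "parity": -0.10, "chronic_hypertension": 0.30,
            "diploma": -0.10, "low_income": 0.20,
        }),
        "lga": OutcomeModel(ln(0.066), {
            "iom_t3_L": ln(0.68), "iom_t3_H": ln(2.26),
            "age_c": 0.015, "parity": 0.12, "smoking": -0.35,
            "chronic_hypertension": 0.10, "prior_diabetes": 0.40, "low_income": -0.05,
        }),
        "hypoglycemia": OutcomeModel(ln(0.011), {
            "iom_t3_L": ln(1.32), "iom_t3_H": ln(1.89),
            "prior_diabetes": 0.80, "smoking": 0.10,
        }),
    }


# Per-group covariate prevalences (group order: lean A, overweight B, obese C).
_GROUP_COVARIATE_P = {
    "smoking": (0.10, 0.12, 0.15),
    "chronic_hypertension": (0.005, 0.015, 0.050),
    "prior_diabetes": (0.003, 0.008, 0.025),
    "diploma": (0.968, 0.960, 0.950),
    "low_income": (0.035, 0.039, 0.052),
}


@dataclass
class SimulationConfig:
    """Everything the cohort generator needs; one seed drives all randomness."""

    n_subjects: int = 6551
    group_shares: tuple[float, ...] = (0.583, 0.324, 0.093)
    #: per-group polynomial coefficients (ascending powers) of mean gain (kg)
    #: versus gestational week; constant term 0 anchors gain at conception.
    group_gain_curves: tuple[tuple[float, ...], ...] = (
        _gain_curve(12.0),
        _gain_curve(14.5),
        _gain_curve(9.0),
    )
    #: per-group between-woman coefficient of variation of the gain curve
    group_gain_cv: tuple[float, ...] = (0.28, 0.25, 0.40)
    #: per-group per-visit measurement noise SD (kg)
    residual_sd: tuple[float, ...] = (1.0, 1.0, 1.0)
    ppbmi_means: tuple[float, ...] = (21.2, 26.3, 35.6)
    ppbmi_sds: tuple[float, ...] = (2.2, 3.1, 5.0)
    height_mean: float = 1.64
    height_sd: float = 0.065
    visit_week_centers: tuple[float, ...] = (10.0, 22.0, 34.0)
    visit_jitter_weeks: float = 2.0
    ga_delivery_mean: float = 39.4
    ga_delivery_sd: float = 1.4
    age_mean: float = 30.0
    age_sd: float = 4.3
    parity_mean: float = 0.9
    #: "absolute" models weight in kg; "gain" models weight minus
    #: pre-pregnancy weight (affects the long-format export only).
    weight_mode: str = "absolute"
    classifier_mode: str = "interpolation"
    outcome_models: dict[str, OutcomeModel] = field(default_factory=_default_outcome_models)
    birthweight_reference: BirthweightReference = field(default_factory=BirthweightReference)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        shares = np.asarray(self.group_shares, dtype=float)
        if shares.ndim != 1 or np.any(shares < 0) or abs(shares.sum() - 1.0) > 1e-8:
            raise ValueError("group_shares must be a probability vector summing to 1")
        J = len(shares)
        for name in ("group_gain_curves", "group_gain_cv", "residual_sd",
                     "ppbmi_means", "ppbmi_sds"):
            if len(getattr(self, name)) != J:
                raise ValueError(f"{name} must have one entry per group ({J})")
        if np.any(np.asarray(self.residual_sd) < 0):
            raise ValueError("residual SDs must be non-negative")
        unknown = set(self.outcome_models) - set(MODELLED_OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcome model(s): {sorted(unknown)}")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        if "outcome_models" in raw:
            raw["outcome_models"] = {
                k: OutcomeModel(v["intercept"], v.get("coefficients", {}))
                for k, v in raw["outcome_models"].items()
            }
        if "birthweight_reference" in raw:
            raw["birthweight_reference"] = BirthweightReference(**raw["birthweight_reference"])
        for name in ("group_shares", "group_gain_cv", "residual_sd", "ppbmi_means",
                     "ppbmi_sds", "visit_week_centers"):
            if name in raw:
                raw[name] = tuple(raw[name])
        if "group_gain_curves" in raw:
            raw["group_gain_curves"] = tuple(tuple(c) for c in raw["group_gain_curves"])
        return cls(**raw)


def default_config(**overrides) -> SimulationConfig:
    """The study-condition defaults, optionally overridden field-by-field."""
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class CohortRecord:
    """One woman of the cohort (the row-wise view of the wide table)."""

    id: str
    pre_pregnancy_weight: float
    height: float
    ppbmi: float
    visits: list[tuple[float, float]]
    age: float
    parity: int
    smoking: int
    chronic_hypertension: int
    prior_diabetes: int
    diploma: int
    low_income: int
    ga_delivery: float
    birth_weight: float | None = None
    outcomes: dict[str, int] = field(default_factory=dict)
    latent_group: int | None = None

    @classmethod
    def from_row(cls, row: Mapping) -> "CohortRecord":
        visits = []
        for t in ("t1", "t2", "t3"):
            ga, wt = row.get(f"ga_{t}"), row.get(f"wt_{t}")
            if ga is not None and wt is not None and np.isfinite(ga) and np.isfinite(wt):
                visits.append((float(ga), float(wt)))
        visits.sort()
        return cls(
            id=str(row["id"]),
            pre_pregnancy_weight=row["pre_pregnancy_weight"],
            height=row["height"],
            ppbmi=row["ppbmi"],
            visits=visits,
            age=row["age"],
            parity=row["parity"],
            smoking=row["smoking"],
            chronic_hypertension=row["chronic_hypertension"],
            prior_diabetes=row["prior_diabetes"],
            diploma=row["diploma"],
            low_income=row["low_income"],
            ga_delivery=row["ga_delivery"],
            birth_weight=row.get("birth_weight"),
            outcomes={k: row[k] for k in OUTCOMES if k in row},
            latent_group=row.get("latent_group"),
        )


def _exposure_features(cohort: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Covariate + exposure-dummy feature table used by the risk models."""
    cls = iom.classify_cohort(cohort, mode=mode)
    feats = cohort[list(COVARIATES)].astype(float).copy()
    feats["age_c"] = feats["age"] - 30.0
    for tri in ("t2", "t3"):
        lab = cls[f"{tri}_label"]
        for lv in ("L", "H"):
            feats[f"iom_{tri}_{lv}"] = (lab == lv).astype(float)
    return feats


def assign_outcomes(
    cohort: pd.DataFrame,
    outcome_models: Mapping[str, OutcomeModel],
    seed: int | np.random.Generator,
    birthweight_reference: BirthweightReference | None = None,
    classifier_mode: str = "interpolation",
) -> pd.DataFrame:
    """Draw outcome flags (and a consistent birth weight) onto a cohort table.

    GDM, HDP, caesarean and hypoglycemia are independent Bernoulli draws from
    their log-linear models.  SGA and LGA are drawn as one three-way
    categorical per woman (SGA / LGA / neither, so the two can never both
    fire) and birth weight is then sampled from the matching region of the
    reference distribution — below the 10th percentile for SGA, above the
    90th for LGA, between otherwise — which keeps the percentile definitions
    and the flags exactly consistent.  Macrosomia is derived as birth weight
    strictly above 4000 g.  Outcomes without a model default to risk 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = birthweight_reference or BirthweightReference()
    feats = _exposure_features(cohort, classifier_mode)
    out = cohort.copy()
    n = len(cohort)

    for name in ("gdm", "hdp", "caesarean", "hypoglycemia"):
        model = outcome_models.get(name)
        p = model.risk(feats) if model is not None else np.zeros(n)
        out[name] = (rng.random(n) < p).astype(np.int8)

    p_sga = outcome_models["sga"].risk(feats) if "sga" in outcome_models else np.zeros(n)
    p_lga = outcome_models["lga"].risk(feats) if "lga" in outcome_models else np.zeros(n)
    total = p_sga + p_lga
    over = total > 1.0
    if over.any():
        warnings.warn("SGA+LGA risks exceeded 1 for some subjects; renormalised",
                      RuntimeWarning, stacklevel=2)
        p_sga = np.where(over, p_sga / total, p_sga)
        p_lga = np.where(over, p_lga / total, p_lga)
    u = rng.random(n)
    sga = u < p_sga
    lga = (~sga) & (u < p_sga + p_lga)
    out["sga"] = sga.astype(np.int8)
    out["lga"] = lga.astype(np.int8)

    ga_del = out["ga_delivery"].to_numpy(dtype=float)
    mu = ref.mean(ga_del)
    z10, z90 = sps.norm.ppf(0.10), sps.norm.ppf(0.90)
    # standard-normal draws truncated to (-inf, z10), (z10, z90) or (z90, inf)
    lo = np.where(sga, -np.inf, np.where(lga, z90, z10))
    hi = np.where(sga, z10, np.where(lga, np.inf, z90))
    q = rng.uniform(sps.norm.cdf(lo), sps.norm.cdf(hi))
    z = sps.norm.ppf(q)
    out["birth_weight"] = mu + ref.sd * z
    out["macrosomia"] = (out["birth_weight"] > MACROSOMIA_CUTOFF_G).astype(np.int8)
    return out


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a complete wide cohort table from ``config`` (deterministic in seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    J = len(config.group_shares)

    group = rng.choice(J, size=n, p=np.asarray(config.group_shares, dtype=float))
    ppbmi = rng.normal(np.asarray(config.ppbmi_means)[group],
                       np.asarray(config.ppbmi_sds)[group])
    ppbmi = np.clip(ppbmi, 14.0, 60.0)
    height = np.clip(rng.normal(config.height_mean, config.height_sd, n), 1.40, 1.95)
    prepreg = ppbmi * height**2

    frailty = rng.normal(1.0, np.asarray(config.group_gain_cv)[group])
    curves = np.zeros((J, max(len(c) for c in config.group_gain_curves)))
    for j, c in enumerate(config.group_gain_curves):
        curves[j, : len(c)] = c

    df = pd.DataFrame({
        "id": [f"S{i:05d}" for i in range(n)],
        "pre_pregnancy_weight": prepreg,
        "height": height,
        "ppbmi": ppbmi,
        "latent_group": group,
    })
    for k, center in enumerate(config.visit_week_centers, start=1):
        ga = np.round(
            center + rng.uniform(-config.visit_jitter_weeks, config.visit_jitter_weeks, n)
        )
        powers = ga[:, None] ** np.arange(curves.shape[1])[None, :]
        mean_gain = (curves[group] * powers).sum(axis=1)
        noise_sd = np.asarray(config.residual_sd)[group]
        noise = rng.normal(0.0, 1.0, n) * noise_sd
        df[f"ga_t{k}"] = ga
        df[f"wt_t{k}"] = prepreg + frailty * mean_gain + noise

    df["ga_delivery"] = np.clip(
        rng.normal(config.ga_delivery_mean, config.ga_delivery_sd, n), 30.0, 42.0
    )
    df["age"] = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 47.0)
    df["parity"] = rng.poisson(config.parity_mean, n)
    for name, probs in _GROUP_COVARIATE_P.items():
        df[name] = (rng.random(n) < np.asarray(probs)[np.minimum(group, 2)]).astype(np.int8)

    df = assign_outcomes(
        df,
        config.outcome_models,
        rng,
        birthweight_reference=config.birthweight_reference,
        classifier_mode=config.classifier_mode,
    )
    return df


def cohort_to_long(
    cohort: pd.DataFrame, weight_mode: str = "absolute", include_week0: bool = True
) -> pd.DataFrame:
    """Wide cohort -> long trajectory table (id, time, y) for trajectory fitting.

    ``weight_mode='absolute'`` returns maternal weight in kg (with the
    pre-pregnancy weight as a week-0 observation when ``include_week0``);
    ``'gain'`` returns weight minus pre-pregnancy weight.
    """
    if weight_mode not in ("absolute", "gain"):
        raise ValueError("weight_mode must be 'absolute' or 'gain'")
    frames = []
    if include_week0:
        frames.append(pd.DataFrame({
            "id": cohort["id"],
            "time": 0.0,
            "y": cohort["pre_pregnancy_weight"].to_numpy(dtype=float),
        }))
    k = 1
    while f"ga_t{k}" in cohort.columns:
        frames.append(pd.DataFrame({
            "id": cohort["id"],
            "time": cohort[f"ga_t{k}"].to_numpy(dtype=float),
            "y": cohort[f"wt_t{k}"].to_numpy(dtype=float),
        }))
        k += 1
    long = pd.concat(frames, ignore_index=True)
    if weight_mode == "gain":
        base = cohort.set_index("id")["pre_pregnancy_weight"]
        long["y"] = long["y"] - base.loc[long["id"]].to_numpy(dtype=float)
    long = long.dropna().sort_values(["id", "time"], kind="stable").reset_index(drop=True)
    return long


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "pre_pregnancy_weight", "height", "ppbmi", "ga_delivery"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks required columns: {sorted(missing)}")
    return df
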