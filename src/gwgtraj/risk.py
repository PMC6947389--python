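"""Relative-risk estimation for binary perinatal outcomes.

Two routes to a relative risk (RR):

* :func:`rr_unadjusted` — closed-form risk ratio from a 2x2 table with the
  Katz log-scale confidence interval;
* :func:`fit_robust_poisson` — modified Poisson regression: a log-link
  Poisson GLM on the binary outcome whose coefficients exponentiate to RRs,
  with a robust (HC0 sandwich) variance estimator replacing the misspecified
  Poisson variance.  This is the standard way to estimate adjusted RRs for
  common binary outcomes, where odds ratios would overstate the association.

Covariate policy: adjusted models use maternal age, parity, smoking during
pregnancy, chronic (pre-pregnancy) hypertension, education (diploma),
family income and pre-existing diabetes — except GDM models, which must not
adjust for pre-existing diabetes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RiskEstimate",
    "rr_unadjusted",
    "fit_robust_poisson",
    "covariate_set",
    "DEFAULT_COVARIATES",
    "GDM_COVARIATES",
]

DEFAULT_COVARIATES = (
    "age",
    "parity",
    "smoking",
    "chronic_hypertension",
    "diploma",
    "low_income",
    "prior_diabetes",
)
#: GDM adjustment never includes pre-existing diabetes.
GDM_COVARIATES = tuple(c for c in DEFAULT_COVARIATES if c != "prior_diabetes")

KNOWN_OUTCOMES = ("gdm", "hdp", "caesarean", "macrosomia", "sga", "lga", "hypoglycemia")

_Z = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class RiskEstimate:
    """One exposure level's relative risk versus the reference level."""

    outcome: str
    exposure_level: str
    reference_level: str
    rr: float
    ci95: tuple[float, float]
    p: float
    adjusted: bool
    covariates: tuple[str, ...] = ()
    n_used: int = 0
    variance: str = "katz"  # "katz" or sandwich variant name
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.rr) and self.rr <= 0:
            raise ValueError("rr must be positive")


def covariate_set(outcome: str) -> tuple[str, ...]:
    """Adjustment covariates for ``outcome`` (GDM excludes pre-existing diabetes)."""
    if outcome not in KNOWN_OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; known: {KNOWN_OUTCOMES}")
    return GDM_COVARIATES if outcome == "gdm" else DEFAULT_COVARIATES


def rr_unadjusted(
    events_exposed: int,
    n_exposed: int,
    events_ref: int,
    n_ref: int,
    outcome: str = "",
    exposure_level: str = "exposed",
    reference_level: str = "reference",
    continuity_correction: bool = False,
) -> RiskEstimate:
    """Risk ratio from counts with the Katz 95% CI.

    CI = exp(log RR +- z * sqrt(1/e1 - 1/n1 + 1/e0 - 1/n0)).  With zero
    events in either arm the estimate is undefined (NaN, flagged) unless
    ``continuity_correction`` adds 0.5 to every cell.
    """
    for v, name in ((events_exposed, "events_exposed"), (n_exposed, "n_exposed"),
                    (events_ref, "events_ref"), (n_ref, "n_ref")):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_exposed == 0 or n_ref == 0:
        raise ValueError("group sizes must be positive")
    if events_exposed > n_exposed or events_ref > n_ref:
        raise ValueError("events cannot exceed group size")
    e1, n1, e0, n0 = map(float, (events_exposed, n_exposed, events_ref, n_ref))
    flags: list[str] = []
    if e1 == 0 or e0 == 0:
        if continuity_correction:
            e1, e0, n1, n0 = e1 + 0.5, e0 + 0.5, n1 + 0.5, n0 + 0.5
            flags.append("continuity_corrected")
        else:
            return RiskEstimate(outcome, exposure_level, reference_level,
                                float("nan"), (float("nan"), float("nan")),
                                float("nan"), adjusted=False,
                                n_used=int(n1 + n0), flags=("zero_events",))
    rr = (e1 / n1) / (e0 / n0)
    se = np.sqrt(1 / e1 - 1 / n1 + 1 / e0 - 1 / n0)
    log_rr = np.log(rr)
    ci = (float(np.exp(log_rr - _Z * se)), float(np.exp(log_rr + _Z * se)))
    p = float(2 * sps.norm.sf(abs(log_rr / se))) if se > 0 else float("nan")
    return RiskEstimate(outcome, exposure_level, reference_level, float(rr), ci, p,
                        adjusted=False, n_used=int(n1 + n0), flags=tuple(flags))


def fit_robust_poisson(
    data: pd.DataFrame,
    outcome: str,
    exposure_factor: str,
    reference: str,
    covariates: Sequence[str] = (),
    levels: Sequence[str] | None = None,
) -> list[RiskEstimate]:
    """Modified Poisson regression of a binary outcome on a categorical exposure.

    Fits a log-link Poisson GLM with HC0 sandwich standard errors and returns
    one :class:`RiskEstimate` per non-reference exposure level (the reference
    level has RR 1 by construction).  Rows missing any model variable are
    dropped (complete case) and ``n_used`` records the analysed count.
    Non-convergence or (near-)separation is flagged, never silent.
    """
    cols = [outcome, exposure_factor, *covariates]
    df = data[cols].dropna()
    y = df[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    obs_levels = pd.unique(df[exposure_factor].astype(str))
    if levels is None:
        levels = [reference] + sorted(lv for lv in obs_levels if lv != reference)
    if reference not in obs_levels:
        raise ValueError(f"reference level {reference!r} absent from data")

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    dummy_cols: dict[str, str] = {}
    for lv in levels:
        if lv == reference:
            continue
        col = f"{exposure_factor}[{lv}]"
        X[col] = (df[exposure_factor].astype(str) == lv).astype(float)
        dummy_cols[lv] = col
    for c in covariates:
        X[c] = df[c].astype(float)

    flags: list[str] = []
    try:
        import warnings as _warnings

        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            model = sm.GLM(y, X, family=sm.families.Poisson())
            res = model.fit(cov_type="HC0", maxiter=300, tol=1e-10)
        if any("eparation" in str(w.message) for w in caught):
            flags.append("possible_separation")
        converged = bool(getattr(res, "converged", True))
    except Exception as exc:  # separation / singular design
        flags.append(f"fit_failed:{type(exc).__name__}")
        res, converged = None, False
    if res is not None and not converged:
        flags.append("not_converged")

    out: list[RiskEstimate] = []
    for lv in levels:
        if lv == reference:
            continue
        col = dummy_cols[lv]
        if res is None or col not in res.params.index:
            out.append(RiskEstimate(outcome, lv, reference, float("nan"),
                                    (float("nan"), float("nan")), float("nan"),
                                    adjusted=bool(covariates),
                                    covariates=tuple(covariates),
                                    n_used=len(df), variance="HC0",
                                    flags=tuple(flags) or ("fit_failed",)))
            continue
        coef = float(res.params[col])
        se = float(res.bse[col])
        lvl_flags = list(flags)
        if not np.isfinite(se) or se > 20 or abs(coef) > 20:
            if "possible_separation" not in lvl_flags:
                lvl_flags.append("possible_separation")
        rr = float(np.exp(coef))
        ci = (float(np.exp(coef - _Z * se)), float(np.exp(coef + _Z * se)))
        p = float(2 * sps.norm.sf(abs(coef / se))) if se > 0 else float("nan")
        out.append(RiskEstimate(outcome, lv, reference, rr, ci, p,
                                adjusted=bool(covariates),
                                covariates=tuple(covariates), n_used=len(df),
                                variance="HC0", flags=tuple(lvl_flags)))
    return out


def risk_table(estimates: Sequence[RiskEstimate]) -> pd.DataFrame:
    """Flatten estimates into a report-friendly table."""
    return pd.DataFrame([
        {
            "outcome": e.outcome,
            "exposure_level": e.exposure_level,
            "reference_level": e.reference_level,
            "rr": e.rr,
            "ci_lo": e.ci95[0],
            "ci_hi": e.ci95[1],
            "p": e.p,
            "adjusted": e.adjusted,
            "covariates": ",".join(e.covariates),
            "n_used": e.n_used,
            "variance": e.variance,
            "flags": ",".join(e.flags),
        }
        for e in estimates
    ])
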