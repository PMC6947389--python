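"""End-to-end study pipeline: simulate/load -> classify -> trajectories -> risks.

Produces a machine-readable study report with the structure of a
gestational-weight-gain cohort analysis:

* cohort composition by WHO ppBMI category, with outcome rates, crude and
  adjusted relative risks, and a trend p-value across categories;
* the same risk tables with second- and third-trimester IOM compliance
  (L/N/H) as the exposure;
* the T2 -> T3 transition table and its normalisation strata;
* trajectory-profile characteristics and profile-exposure risk tables from
  the selected group-based trajectory model.

Every percentage in the report is recomputable from the emitted counts, and
the provenance block (seed, config hash, versions) plus deterministic JSON
serialisation make identical configurations byte-identical on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, gbtm, iom, risk, simulate, stats

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

log = logging.getLogger("gwgtraj.pipeline")

OUTCOME_ORDER = simulate.OUTCOMES


@dataclass
class PipelineConfig:
    """Exactly one of ``input_csv`` / ``sim_config`` drives the pipeline."""

    input_csv: str | None = None
    sim_config: simulate.SimulationConfig | None = None
    classifier_mode: str = "interpolation"
    gbtm_J_range: tuple[int, ...] = (1, 2, 3)
    gbtm_order_range: tuple[int, ...] = (1,)
    gbtm_n_starts: int = 4
    gbtm_weight_mode: str = "absolute"
    seed: int = 0
    outcomes: tuple[str, ...] = OUTCOME_ORDER
    out_dir: str | None = None
    make_plot: bool = False

    def validate(self) -> None:
        if (self.input_csv is None) == (self.sim_config is None):
            raise ValueError("set exactly one of input_csv / sim_config")
        unknown = set(self.outcomes) - set(OUTCOME_ORDER)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")

    def content_hash(self) -> str:
        payload = dataclasses.asdict(self)
        # only analysis-relevant fields: where the report is written (and
        # whether a plot is drawn) must not change its identity
        payload.pop("out_dir", None)
        payload.pop("make_plot", None)
        if self.sim_config is not None:
            payload["sim_config"] = json.loads(self.sim_config.to_json())
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def _risk_block(df: pd.DataFrame, exposure_col: str, levels: list[str],
                reference: str, outcomes) -> dict:
    """Counts, rates, crude RR, adjusted RR and trend p for one exposure."""
    sub = df[df[exposure_col].notna()]
    n_by = {lv: int((sub[exposure_col] == lv).sum()) for lv in levels}
    n_total = sum(n_by.values())
    block = {
        "exposure": exposure_col,
        "reference": reference,
        "n": n_total,
        "levels": {
            lv: {"n": n_by[lv],
                 "pct": 100.0 * n_by[lv] / n_total if n_total else float("nan")}
            for lv in levels
        },
        "outcomes": {},
    }
    for outcome in outcomes:
        events = {lv: int(sub.loc[sub[exposure_col] == lv, outcome].sum())
                  for lv in levels}
        entry = {
            "events": events,
            "rate_pct": {lv: 100.0 * events[lv] / n_by[lv] if n_by[lv] else float("nan")
                         for lv in levels},
        }
        try:
            trend = stats.trend_test([events[lv] for lv in levels],
                                     [n_by[lv] for lv in levels], labels=levels)
            entry["trend_p"] = trend.p
        except ValueError:
            entry["trend_p"] = None
        crude = []
        for lv in levels:
            if lv == reference:
                continue
            est = risk.rr_unadjusted(events[lv], n_by[lv], events[reference],
                                     n_by[reference], outcome=outcome,
                                     exposure_level=lv, reference_level=reference)
            crude.append(est)
        adjusted = risk.fit_robust_poisson(
            sub, outcome, exposure_col, reference,
            covariates=risk.covariate_set(outcome), levels=levels,
        )
        entry["rr"] = {e.exposure_level: {"rr": e.rr, "ci": list(e.ci95), "p": e.p}
                       for e in crude}
        entry["arr"] = {e.exposure_level: {"rr": e.rr, "ci": list(e.ci95), "p": e.p,
                                           "n_used": e.n_used,
                                           "flags": list(e.flags)}
                        for e in adjusted}
        block["outcomes"][outcome] = entry
    return block


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the study report (a plain dict)."""
    config.validate()
    # --- input -----------------------------------------------------------
    if config.sim_config is not None:
        log.info("simulating cohort (n=%d, seed=%d)",
                 config.sim_config.n_subjects, config.sim_config.seed)
        cohort = simulate.generate_cohort(config.sim_config)
    else:
        log.info("loading cohort from %s", config.input_csv)
        cohort = simulate.read_cohort_csv(config.input_csv)

    # --- exclusion accounting (flow-chart style), emitted first ----------
    cls = iom.classify_cohort(cohort, mode=config.classifier_mode)
    fully_excluded = cls["category"].isna() | (
        cls["t2_label"].isna() & cls["t3_label"].isna()
    )
    exclusions = {
        "n_input": int(len(cohort)),
        "n_analyzed": int((~fully_excluded).sum()),
        "n_excluded": int(fully_excluded.sum()),
        "reasons": cls.loc[fully_excluded, "exclusion"].value_counts().to_dict(),
        "excluded_ids": cohort.loc[fully_excluded, "id"].astype(str).tolist(),
    }
    log.info("exclusions: %d of %d records", exclusions["n_excluded"], len(cohort))
    cohort = cohort.loc[~fully_excluded].reset_index(drop=True)
    cls = cls.loc[~fully_excluded].reset_index(drop=True)
    df = cohort.copy()
    df["ppbmi_category"] = cls["category"]
    df["iom_t2"] = cls["t2_label"]
    df["iom_t3"] = cls["t3_label"]

    report: dict = {"exclusions": exclusions}

    # --- cohort composition / ppBMI risk table ----------------------------
    cat_levels = [c.value for c in iom.CATEGORY_ORDER]
    report["ppbmi_table"] = _risk_block(df, "ppbmi_category", cat_levels,
                                        "normal", config.outcomes)

    # --- IOM T2 / T3 tables ----------------------------------------------
    for tri in ("t2", "t3"):
        report[f"iom_{tri}_table"] = _risk_block(
            df, f"iom_{tri}", ["L", "N", "H"], "N", config.outcomes
        )

    # --- transition strata -------------------------------------------------
    both = df[df["iom_t2"].notna() & df["iom_t3"].notna()]
    trans = iom.transition_table(both["iom_t2"], both["iom_t3"])
    strata_outcomes = {}
    for row_label, t2_key in (("H", "T2H"), ("N", "T2N")):
        in_row = both[both["iom_t2"] == row_label]
        stayed = in_row[in_row["iom_t3"] == "H"] if t2_key == "T2H" else \
            in_row[in_row["iom_t3"] != "H"]
        changed = in_row.drop(stayed.index)
        strata_outcomes[t2_key] = {}
        for outcome in config.outcomes:
            a, b = changed[outcome], stayed[outcome]
            tab = np.array([[a.sum(), len(a) - a.sum()],
                            [b.sum(), len(b) - b.sum()]], dtype=float)
            try:
                comp = stats.compare_categorical(tab)
                p = comp["p"]
            except ValueError:
                p = None
            strata_outcomes[t2_key][outcome] = {
                "changed_rate_pct": 100.0 * a.mean() if len(a) else None,
                "stayed_rate_pct": 100.0 * b.mean() if len(b) else None,
                "p": p,
            }
    report["transition_table"] = {
        "n": trans.n,
        "counts": {f"{a}->{b}": trans.cell(a, b)
                   for a in iom.LABELS for b in iom.LABELS},
        "strata": trans.strata,
        "strata_outcomes": strata_outcomes,
    }

    # --- trajectory modelling ----------------------------------------------
    long = simulate.cohort_to_long(df, weight_mode=config.gbtm_weight_mode)
    log.info("fitting trajectory models: J in %s, order in %s",
             config.gbtm_J_range, config.gbtm_order_range)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit, sweep = gbtm.select_model(
            long, J_range=config.gbtm_J_range, order_range=config.gbtm_order_range,
            seed=config.seed, n_starts=config.gbtm_n_starts,
        )
    profile_of = pd.Series(
        [chr(65 + g) for g in fit.assignment], index=fit.subject_ids
    )
    df["profile"] = profile_of.loc[df["id"]].to_numpy()
    slopes, slope_pairs = gbtm.trajectory_slopes(fit, long)
    report["gbtm"] = {
        "selected_J": fit.spec.J,
        "selected_order": fit.spec.order,
        "bic_table": sweep.drop(columns=["error"]).to_dict(orient="records"),
        "pi": fit.pi.tolist(),
        "beta": fit.beta.tolist(),
        "sigma": fit.sigma.tolist(),
        "loglik": fit.loglik,
        "bic": fit.bic,
        "adequacy": fit.diagnostics.to_dict(orient="records"),
        "slopes": slopes.to_dict(orient="records"),
        "slope_pairs": slope_pairs.to_dict(orient="records"),
        "weight_mode": config.gbtm_weight_mode,
    }

    # --- profile characteristics (trajectory-group table) ------------------
    profiles = sorted(df["profile"].unique())
    prof_block: dict = {"n": int(len(df)), "profiles": {}}
    for p_lab in profiles:
        sub = df[df["profile"] == p_lab]
        gains = {}
        for k, tri in ((1, "t1"), (2, "t2"), (3, "t3")):
            g = (sub[f"wt_t{k}"] - sub["pre_pregnancy_weight"]).dropna()
            if len(g):
                gains[tri] = {
                    "median": float(g.median()), "min": float(g.min()),
                    "max": float(g.max()),
                    "iqr": [float(g.quantile(0.25)), float(g.quantile(0.75))],
                }
        prof_block["profiles"][p_lab] = {
            "n": int(len(sub)),
            "pct": 100.0 * len(sub) / len(df),
            "age_mean": float(sub["age"].mean()),
            "age_sd": float(sub["age"].std()),
            "ppbmi_mean": float(sub["ppbmi"].mean()),
            "ppbmi_sd": float(sub["ppbmi"].std()),
            "ppbmi_category_pct": {
                c: 100.0 * float((sub["ppbmi_category"] == c).mean())
                for c in cat_levels
            },
            "gains": gains,
        }
    if len(profiles) >= 2:
        comp = stats.compare_continuous(
            {p: df.loc[df["profile"] == p, "ppbmi"].to_numpy() for p in profiles}
        )
        prof_block["ppbmi_comparison"] = {
            "test": comp.omnibus_test, "p": comp.omnibus_p,
            "posthoc_method": comp.posthoc_method,
        }
    report["profile_table"] = prof_block

    # --- profile risk table -------------------------------------------------
    if len(profiles) >= 2:
        report["profile_risk_table"] = _risk_block(
            df, "profile", profiles, profiles[0], config.outcomes
        )

    # --- provenance -----------------------------------------------------------
    report["provenance"] = {
        "package": "gwgtraj",
        "version": __version__,
        "seed": config.seed,
        "classifier_mode": config.classifier_mode,
        "config_hash": config.content_hash(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }

    if config.out_dir is not None:
        write_report(report, df, config, fit=fit, long=long)
    return _round_floats(report)


def write_report(report: dict, df: pd.DataFrame, config: PipelineConfig,
                 fit=None, long=None) -> None:
    """Write report JSON plus per-table CSVs (and optional trajectory plot)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(_round_floats(report), fh, sort_keys=True, indent=1)
    df.to_csv(out / "cohort_analyzed.csv", index=False)
    if fit is not None:
        pd.DataFrame(
            fit.posterior,
            columns=[f"profile_{chr(65 + j)}" for j in range(fit.spec.J)],
        ).assign(id=fit.subject_ids).to_csv(out / "posterior.csv", index=False)
    for key in ("ppbmi_table", "iom_t2_table", "iom_t3_table", "profile_risk_table"):
        if key not in report:
            continue
        rows = []
        block = report[key]
        for outcome, entry in block["outcomes"].items():
            for lv in block["levels"]:
                rec = {
                    "outcome": outcome, "level": lv,
                    "n": block["levels"][lv]["n"],
                    "events": entry["events"][lv],
                    "rate_pct": entry["rate_pct"][lv],
                    "trend_p": entry.get("trend_p"),
                }
                if lv in entry["rr"]:
                    rec.update(rr=entry["rr"][lv]["rr"],
                               rr_lo=entry["rr"][lv]["ci"][0],
                               rr_hi=entry["rr"][lv]["ci"][1])
                if lv in entry["arr"]:
                    rec.update(arr=entry["arr"][lv]["rr"],
                               arr_lo=entry["arr"][lv]["ci"][0],
                               arr_hi=entry["arr"][lv]["ci"][1])
                rows.append(rec)
        pd.DataFrame(rows).to_csv(out / f"{key}.csv", index=False)
    if config.make_plot and fit is not None and long is not None:
        gbtm.plot_trajectories(fit, long, out / "trajectories.png")
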