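"""Model evaluation: goodness of fit, SREs, metabolic scaling, reports.

Goodness of fit between predicted and observed series uses the
efficiency-style statistic

    GF = 1 - sum((O_i - E_i)^2) / sum((O_i - mean(O))^2),

which equals 1 for a perfect fit, 0 for a predictor no better than the
observed mean, and may be negative for worse-than-mean predictions
(reported as-is).

The module also houses the full pipeline: preprocess a raw table, run all
calibration stages per sex, insert the fitted parameters into the growth
model, integrate, and score the predictions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MGMParams, ingestion_rate
from .estimate import (
    FitResult,
    fit_hockey_stick,
    fit_ingestion_adult,
    fit_ingestion_juvenile,
    fit_inverse_growth,
    infer_feeding_cost_series,
    rising_phase_records,
)
from .preprocess import ProcessedSeries, process_table, sex_average
from .simulate import activity_scope, fit_loglog_allometry, integrate_growth

__all__ = [
    "PipelineConfig",
    "EvaluationReport",
    "goodness_of_fit",
    "standardized_random_effect",
    "indirect_total_metabolic_rate",
    "evaluate_model",
    "run_pipeline",
]


def goodness_of_fit(observed, predicted) -> float:
    """GF = 1 - SS_res/SS_tot about the observed mean.

    Undefined (raises) for constant observed series; negative values are
    informative and not clipped.
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(predicted, dtype=float)
    if O.shape != E.shape or O.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    ss_tot = float(((O - O.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("GF undefined for a constant observed series")
    ss_res = float(((O - E) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def standardized_random_effect(random_effects, fixed_effect: float) -> float:
    """SRE = sd(RE)/|FE|: individual variation relative to the fixed effect."""
    re = np.asarray(list(random_effects.values())
                    if isinstance(random_effects, dict) else random_effects,
                    dtype=float)
    if re.size < 2:
        raise ValueError("need at least 2 random effects")
    if fixed_effect == 0:
        raise ValueError("SRE undefined for a zero fixed effect")
    return float(re.std(ddof=1) / abs(fixed_effect))


def indirect_total_metabolic_rate(
    series: list[ProcessedSeries], e: float, E_M: float
) -> pd.DataFrame:
    """Empirical total metabolic rate, R_tot = e*S - E_M*dW/dt per record.

    Total metabolism is not measured directly; it is the difference between
    assimilation and the energy flux stored in biomass.
    """
    rows = []
    for s in series:
        n = min(s.S.size, s.W_at_S.size, s.dWdt_at_S.size)
        if n == 0:
            continue
        ok = np.isfinite(s.S[:n]) & np.isfinite(s.dWdt_at_S[:n])
        rows.append(pd.DataFrame({
            "id": s.id, "sex": s.sex, "age_mid_d": s.S_ages[:n][ok],
            "W_mg": s.W_at_S[:n][ok],
            "R_tot_J_d": e * s.S[:n][ok] - E_M * s.dWdt_at_S[:n][ok],
        }))
    if not rows:
        raise ValueError("no records with aligned S and dW/dt")
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PipelineConfig:
    """Externally supplied (literature-derived) constants and options."""

    e: float = 0.8          # assimilation efficiency
    E_M: float = 6.0        # biomass energy density, J/mg
    a_R: float = 0.75       # resting-metabolism normalization, J/day/mg^b_R
    b_R: float = 0.9        # resting-metabolism exponent
    E_f: float = 17.0       # food energy density, J/mg dry
    moisture_uptake: float = 0.15
    egestion_fraction: float | None = None  # None: estimate from data
    smoothing_window: int = 3
    n_starts: int = 16      # inverse-optimization multi-starts

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class EvaluationReport:
    """Collected evaluation results for one calibrated dataset."""

    gf_sex_averaged: dict[str, float] = field(default_factory=dict)
    gf_individual: dict[str, dict[str, float]] = field(default_factory=dict)
    gf_individual_mean: dict[str, float] = field(default_factory=dict)
    sre_table: dict[str, dict[str, float]] = field(default_factory=dict)
    b_T: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    activity_scope: dict[str, dict[str, float]] = field(default_factory=dict)
    recovery: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    fitted_params: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _assemble_params(
    sex: str,
    config: PipelineConfig,
    juv: FitResult,
    adult: FitResult,
    hockey: FitResult,
    inverse: FitResult,
    W_mat: float,
    W_0: float,
) -> MGMParams:
    kw = (
        {"gamma_B": inverse.params["gamma_B"]}
        if sex == "male"
        else {"gamma_BS": inverse.params["gamma_BS"],
              "gamma_BR": inverse.params["gamma_BR"]}
    )
    return MGMParams(
        sex=sex, e=config.e, E_M=config.E_M, E_S=inverse.params["E_S"],
        alpha=juv.params["alpha"], beta=juv.params["beta"],
        k=adult.params["k"], W_star=adult.params["W_star"],
        W_mat=W_mat, S1=hockey.params["S1"],
        kF1=hockey.params["kF1"], kF2=hockey.params["kF2"],
        a_N=inverse.params["a_N"], a_R=config.a_R, b_R=config.b_R,
        W_0=W_0, **kw,
    )


def evaluate_model(
    series: list[ProcessedSeries],
    fitted: dict[str, MGMParams],
    config: PipelineConfig,
    fits: dict[str, dict[str, FitResult]] | None = None,
    raw: pd.DataFrame | None = None,
) -> EvaluationReport:
    """Integrate the fitted model and score it against the data.

    Sex-averaged GF compares the fixed-effects trajectory with the
    averaged empirical mass curve on the common occasion grid.
    Per-individual GF uses each individual's own (raw, unsmoothed when
    ``raw`` is given) masses against a prediction started from that
    individual's first mass.  Scaling exponents b_T are fitted on the two
    juvenile windows, for both model-predicted and indirect-empirical
    total metabolic rate.
    """
    report = EvaluationReport()
    averaged = sex_average(series)
    indirect = indirect_total_metabolic_rate(series, config.e, config.E_M)
    for sex, p in fitted.items():
        avg = averaged[sex]
        occ = avg[np.isfinite(avg["W_mg"])]
        ages = occ["age_d"].to_numpy(dtype=float)
        W_obs = occ["W_mg"].to_numpy(dtype=float)
        traj = integrate_growth(p, (float(ages[0]), float(ages[-1])),
                                form="full", t_eval=ages)
        report.gf_sex_averaged[sex] = goodness_of_fit(W_obs, traj.W)
        report.fitted_params[sex] = p.to_dict()

        # per-individual GF: fixed effects, individual initial mass
        per = {}
        for s in (x for x in series if x.sex == sex):
            if raw is not None:
                g = raw[raw["id"] == s.id].sort_values("age_d")
                o_ages = g["age_d"].to_numpy(dtype=float)
                O = g["mass_mg"].to_numpy(dtype=float)
            else:
                o_ages, O = s.ages, s.W
            p_i = p.replace(W_0=float(max(O[0], 1e-3)))
            t_i = integrate_growth(p_i, (float(o_ages[0]), float(o_ages[-1])),
                                   form="full", t_eval=o_ages)
            per[s.id] = goodness_of_fit(O, t_i.W)
        report.gf_individual[sex] = per
        report.gf_individual_mean[sex] = float(np.mean(list(per.values())))

        # metabolic scaling windows: whole juvenile interval and S <= S1
        dense = integrate_growth(p, (float(ages[0]), float(ages[-1])),
                                 form="full",
                                 t_eval=np.linspace(ages[0], ages[-1], 600))
        W_S1 = (p.S1 / p.alpha) ** (1.0 / p.beta)  # juvenile mass where S = S1
        ind_sex = indirect[indirect["sex"] == sex]
        report.b_T[sex] = {}
        for name, hi in (("W<=W_mat", p.W_mat), ("S<=S1", min(W_S1, p.W_mat))):
            window = (0.0, hi)
            entry = {}
            mask = dense.R_tot > 0
            entry["model"] = fit_loglog_allometry(
                dense.W[mask], dense.R_tot[mask], window)["b_T"]
            emp = ind_sex[(ind_sex["R_tot_J_d"] > 0) & (ind_sex["W_mg"] <= hi)]
            if len(emp) >= 3:
                entry["indirect"] = fit_loglog_allometry(
                    emp["W_mg"], emp["R_tot_J_d"], window)["b_T"]
            report.b_T[sex][name] = entry

        scope = activity_scope(dense)
        report.activity_scope[sex] = {"min": scope["min"], "max": scope["max"]}

        if fits is not None:
            for stage, fr in fits[sex].items():
                for pname, sre in fr.sre.items():
                    report.sre_table.setdefault(sex, {})[f"{stage}.{pname}"] = sre
    return report


def run_pipeline(
    raw: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int = 0,
    truth: dict | None = None,
    per_individual: bool = True,
) -> dict:
    """Complete calibration and evaluation for a raw experiment table.

    Returns a dict with the processed series, per-sex stage fits, the
    assembled parameter sets and the evaluation report.  When generator
    truth metadata is supplied, a recovery table (truth vs estimate,
    relative errors) is added to the report.
    """
    config = config or PipelineConfig()
    series = process_table(
        raw, m=config.moisture_uptake, E_f=config.E_f,
        r=config.egestion_fraction, window=config.smoothing_window,
    )
    fits: dict[str, dict[str, FitResult]] = {}
    fitted: dict[str, MGMParams] = {}
    for sex in sorted({s.sex for s in series}):
        group = [s for s in series if s.sex == sex]
        juv = fit_ingestion_juvenile(group)
        adult = fit_ingestion_adult(group, juv.params["alpha"], juv.params["beta"])
        rf = rising_phase_records(
            infer_feeding_cost_series(group, config.e, config.E_M,
                                      config.a_R, config.b_R)
        )
        hockey = fit_hockey_stick(rf["S_J_d"], rf["R_F_J_d"], groups=rf["id"])
        inverse = fit_inverse_growth(
            group, config.a_R, config.b_R, sex, E_M=config.E_M,
            n_starts=config.n_starts, seed=seed, per_individual=per_individual,
        )
        fits[sex] = {"ingestion_juvenile": juv, "ingestion_adult": adult,
                     "feeding_cost": hockey, "inverse": inverse}
        W_mat = inverse.extras["W_mat"]
        W_0 = inverse.extras["W_0"]
        fitted[sex] = _assemble_params(sex, config, juv, adult, hockey,
                                       inverse, W_mat, W_0)
    report = evaluate_model(series, fitted, config, fits=fits, raw=raw)
    if truth is not None:
        report.recovery = recovery_table(fits, truth)
    return {"series": series, "fits": fits, "fitted_params": fitted,
            "report": report, "config": config}


def recovery_table(
    fits: dict[str, dict[str, FitResult]], truth: dict
) -> dict[str, dict[str, dict[str, float]]]:
    """Compare estimated fixed effects with generator-truth templates."""
    stage_param = {
        "alpha": "ingestion_juvenile", "beta": "ingestion_juvenile",
        "k": "ingestion_adult", "W_star": "ingestion_adult",
        "kF1": "feeding_cost", "kF2": "feeding_cost", "S1": "feeding_cost",
        "E_S": "inverse", "gamma_B": "inverse", "gamma_BS": "inverse",
        "gamma_BR": "inverse", "a_N": "inverse",
    }
    out: dict[str, dict[str, dict[str, float]]] = {}
    for sex, stages in fits.items():
        template = truth["templates"][sex]
        table = {}
        for pname, stage in stage_param.items():
            if pname not in template or stage not in stages:
                continue
            fr = stages[stage]
            if pname not in fr.params:
                continue
            t, est = float(template[pname]), float(fr.params[pname])
            table[pname] = {
                "truth": t, "estimate": est,
                "rel_err": (est - t) / t if t != 0 else float("nan"),
            }
        out[sex] = table
    return out
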