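"""Multi-stage parameter calibration.

The pipeline estimates the model's parameter groups in the order their
dependencies allow, each stage analysed per sex:

1. juvenile ingestion allometry (alpha, beta) — log-log regression with a
   shared slope and per-individual intercepts (two-stage scheme standing in
   for a linear mixed model);
2. adult ingestion branch (k, W_star) — bounded nonlinear least squares
   with the juvenile parameters held fixed;
3. feeding costs (kF1, kF2, S1) — per-record feeding costs inferred from
   the energy balance using a literature resting-metabolism allometry,
   then a constrained continuous hockey-stick fit with profiled breakpoint;
4. inverse calibration of (E_S, gamma_B, a_N) for males and
   (E_S, gamma_BS, gamma_BR, a_N) for females — least-squares fit of the
   resting-form growth equation to observed mass curves, multi-start
   bounded optimization on the sex-averaged curve (stage 1) followed by
   per-individual refits that yield random effects (stage 2).

Individual variation is summarized by the standardized random effect,
``SRE = sd(RE)/|FE|`` — a coefficient-of-variation analogue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, nnls
from scipy.stats import qmc

from .core import MGMParams, ParameterError, ValidityDomainError, maintenance_cost
from .preprocess import ProcessedSeries, sex_average

__all__ = [
    "FitResult",
    "fit_ingestion_juvenile",
    "fit_ingestion_adult",
    "infer_feeding_cost_series",
    "fit_hockey_stick",
    "fit_inverse_growth",
]

log = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Fixed effects, random effects and diagnostics for one fit stage."""

    params: dict[str, float]
    random_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    re_sd: dict[str, float] = field(default_factory=dict)
    sre: dict[str, float] = field(default_factory=dict)
    objective: float = float("nan")
    converged: bool = True
    n_obs: int = 0
    message: str = ""
    extras: dict = field(default_factory=dict)

    def finalize_sres(self) -> None:
        """(Re)compute SRE = sd(RE)/|FE| from the stored random effects."""
        for name, res in self.random_effects.items():
            vals = np.array(list(res.values()), dtype=float)
            if vals.size >= 2 and self.params.get(name, 0.0) != 0.0:
                self.re_sd[name] = float(vals.std(ddof=1))
                self.sre[name] = self.re_sd[name] / abs(self.params[name])

    def to_json(self) -> str:
        payload = {
            "params": self.params,
            "random_effects": self.random_effects,
            "re_sd": self.re_sd,
            "sre": self.sre,
            "objective": self.objective,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "message": self.message,
        }
        return json.dumps(payload, indent=1)


def _juvenile_records(s: ProcessedSeries) -> tuple[np.ndarray, np.ndarray]:
    mask = s.juvenile_mask_at_S() & (s.S > 0) & (s.W_at_S > 0)
    return s.W_at_S[mask], s.S[mask]


def fit_ingestion_juvenile(
    series: list[ProcessedSeries], min_points: int = 3
) -> FitResult:
    """Juvenile ingestion allometry S = alpha*W**beta, one sex at a time.

    Two-stage hierarchical scheme: per-individual OLS of log10(S) on
    log10(W), precision-weighted pooling of the slopes into a shared fixed
    effect beta, then per-individual intercepts at the pooled slope whose
    spread gives the random-effect SD of log10(alpha).  Individuals with
    fewer than ``min_points`` juvenile records are dropped (logged).
    """
    sexes = {s.sex for s in series}
    if len(sexes) != 1:
        raise ValueError(
            f"ingestion fits are per sex; got {sorted(sexes)} — split the input"
        )
    slopes, weights, per_ind = [], [], {}
    n_obs = 0
    for s in series:
        W, S = _juvenile_records(s)
        if W.size < min_points:
            log.info("dropping %s: only %d juvenile ingestion records", s.id, W.size)
            continue
        X = sm.add_constant(np.log10(W))
        res = sm.OLS(np.log10(S), X).fit()
        slopes.append(res.params[1])
        se = res.bse[1] if np.isfinite(res.bse[1]) and res.bse[1] > 0 else np.nan
        weights.append(1.0 / se**2 if np.isfinite(se) else np.nan)
        per_ind[s.id] = (np.log10(W), np.log10(S))
        n_obs += W.size
    if not slopes:
        raise ValueError("no individual had enough juvenile ingestion records")
    slopes = np.asarray(slopes)
    weights = np.asarray(weights)
    if not np.all(np.isfinite(weights)):  # exact data: equal weights
        weights = np.ones_like(slopes)
    beta = float(np.sum(weights * slopes) / np.sum(weights))
    intercepts = {
        ind: float(np.mean(lS - beta * lW)) for ind, (lW, lS) in per_ind.items()
    }
    fe_intercept = float(np.mean(list(intercepts.values())))
    result = FitResult(
        params={"alpha": float(10.0**fe_intercept), "beta": beta,
                "log10_alpha": fe_intercept},
        random_effects={"log10_alpha": {i: v - fe_intercept for i, v in intercepts.items()}},
        n_obs=n_obs,
        extras={"slope_sd": float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0,
                "n_individuals": len(per_ind)},
    )
    result.finalize_sres()
    # for the normalization itself, SRE on the natural scale
    alphas = np.array([10.0**v for v in intercepts.values()])
    if alphas.size >= 2:
        result.sre["alpha"] = float(alphas.std(ddof=1) / alphas.mean())
    return result


def _adult_branch(W, alpha, beta, k, W_star, W_mat):
    S_mat = alpha * W_mat**beta
    return S_mat + k * (
        W_star * (W**beta - W_mat**beta) / beta
        - (W ** (1 + beta) - W_mat ** (1 + beta)) / (1 + beta)
    )


def fit_ingestion_adult(
    series: list[ProcessedSeries],
    alpha: float,
    beta: float,
    n_grid: int = 8,
) -> FitResult:
    """Adult ingestion branch (k, W_star) by bounded nonlinear least squares.

    Pools all post-maturity ingestion records of one sex; each record uses
    its individual's maturity mass in the branch formula, with alpha and
    beta held at the juvenile fit.  Multi-start over a coarse W_star grid
    that always includes the mass at the empirical ingestion peak.
    """
    recs = []
    for s in series:
        if s.maturity_age is None:
            continue
        mask = ~s.juvenile_mask_at_S() & (s.S > 0)
        Wm = s.maturity_mass
        for W, S in zip(s.W_at_S[mask], s.S[mask]):
            if W > Wm:
                recs.append((W, S, Wm))
    if not recs:
        raise ValueError("no post-maturity ingestion records")
    W = np.array([r[0] for r in recs])
    S = np.array([r[1] for r in recs])
    Wm = np.array([r[2] for r in recs])

    def resid(x):
        k, W_star = x
        return _adult_branch(W, alpha, beta, k, W_star, Wm) - S

    W_peak = float(W[np.argmax(S)])
    Wmax = float(W.max())
    starts = sorted({W_peak, *np.linspace(Wm.mean() * 1.05, Wmax * 1.5, n_grid)})
    best = None
    for w0 in starts:
        try:
            res = least_squares(
                resid, x0=[0.01, w0],
                bounds=([1e-9, float(Wm.min()) * 1.001], [10.0, Wmax * 10]),
            )
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all starts of the adult ingestion fit failed")
    k, W_star = best.x
    sse = float(2 * best.cost)
    # crude spread diagnostic: weak adult patterns give wide residuals
    rel_resid = np.sqrt(sse / S.size) / S.mean()
    return FitResult(
        params={"k": float(k), "W_star": float(W_star)},
        objective=sse, n_obs=S.size, converged=bool(best.success),
        message="weak adult ingestion pattern" if rel_resid > 0.25 else "",
        extras={"relative_residual": float(rel_resid), "W_peak_start": W_peak},
    )


def infer_feeding_cost_series(
    series: list[ProcessedSeries],
    e: float,
    E_M: float,
    a_R: float,
    b_R: float,
) -> pd.DataFrame:
    """Per-record feeding costs from the energy balance.

    ``R_F = e*S - E_M*dW/dt - a_R*W**b_R`` — assimilation minus the energy
    flux bound into biomass minus resting metabolism (power-allometry
    approximation).  S, W and dW/dt come aligned at interval midpoints of
    the smoothed series.
    """
    rows = []
    for s in series:
        n = min(s.S.size, s.W_at_S.size, s.dWdt_at_S.size)
        if n == 0:
            continue
        S, W, dW = s.S[:n], s.W_at_S[:n], s.dWdt_at_S[:n]
        ok = np.isfinite(S) & np.isfinite(W) & np.isfinite(dW) & (S > 0) & (W > 0)
        RF = e * S[ok] - E_M * dW[ok] - a_R * W[ok] ** b_R
        rows.append(pd.DataFrame({
            "id": s.id, "sex": s.sex, "age_mid_d": s.S_ages[:n][ok],
            "W_mg": W[ok], "S_J_d": S[ok], "R_F_J_d": RF,
        }))
    if not rows:
        raise ValueError("no aligned S/W/dWdt records available")
    return pd.concat(rows, ignore_index=True)


def rising_phase_records(rf: pd.DataFrame) -> pd.DataFrame:
    """Restrict feeding-cost records to each individual's rising-S phase.

    Ingestion rises with mass up to the post-maturity peak and declines
    beyond it, so the map S(W) — and with it the feeding-cost relation
    R_F(S) — is only single-valued up to the peak.  Records after an
    individual's empirical ingestion peak would re-enter low S values
    with the metabolism of a much larger animal and confound the
    breakpoint fit.
    """
    keep = []
    for _, g in rf.groupby("id", sort=False):
        g = g.sort_values("age_mid_d")
        ipk = int(np.argmax(g["S_J_d"].to_numpy()))
        keep.append(g.iloc[: ipk + 1])
    return pd.concat(keep, ignore_index=True)


def fit_hockey_stick(
    S, R_F, groups=None, n_profile: int | None = None
) -> FitResult:
    """Continuous two-slope feeding-cost fit with profiled breakpoint.

    Model: ``R_F = kF1*S`` for ``S <= S1`` and
    ``kF1*S1 + kF2*(S - S1)`` above, with the first segment through the
    origin and ``kF2 >= kF1 >= 0`` enforced.  The breakpoint is profiled
    over the observed S values (ties broken toward smaller S1); at each
    candidate the slopes come from nonnegative least squares on the
    reparametrization ``R_F = kF1*S + (kF2 - kF1)*(S - S1)_+``.

    With ``groups`` (individual labels per record) the slopes become
    per-individual while the breakpoint stays shared: the two-stage analog
    of a random-slopes mixed model.  Individual feeding records shift as a
    block when an individual eats systematically more or less than
    average, so pooling without individual effects confounds the
    between-individual spread with the within-individual slope; the
    grouped fit estimates the slopes within individuals.  Fixed effects
    are record-count-weighted means of the individual slopes, whose
    spread yields the random-effect SDs.
    """
    S = np.asarray(S, dtype=float)
    R_F = np.asarray(R_F, dtype=float)
    ok = np.isfinite(S) & np.isfinite(R_F)
    if groups is not None:
        groups = np.asarray(groups)[ok]
    S, R_F = S[ok], R_F[ok]
    if S.size < 6:
        raise ValueError("need at least 6 points to fit a broken line")
    candidates = np.unique(S)
    if candidates.size < 2 or S.max() <= S.min():
        raise ValueError("degenerate ingestion range")
    if n_profile is None and groups is not None:
        n_profile = 60  # grouped profiling is heavier; a quantile grid suffices
    if n_profile is not None and candidates.size > n_profile:
        candidates = np.unique(np.quantile(candidates, np.linspace(0, 1, n_profile)))

    def fit_at(S1: float):
        """(sse, per-group coef dict) at a fixed breakpoint."""
        if groups is None:
            A = np.column_stack([S, np.clip(S - S1, 0.0, None)])
            coef, _ = nnls(A, R_F)
            return float(((A @ coef - R_F) ** 2).sum()), {None: (coef, S.size)}
        sse, per = 0.0, {}
        for gid in np.unique(groups):
            m = groups == gid
            A = np.column_stack([S[m], np.clip(S[m] - S1, 0.0, None)])
            coef, _ = nnls(A, R_F[m])
            sse += float(((A @ coef - R_F[m]) ** 2).sum())
            per[gid] = (coef, int(m.sum()))
        return sse, per

    best = None
    for S1 in candidates:
        sse, per = fit_at(float(S1))
        if best is None or sse < best[0] - 1e-12:  # strict: ties keep smaller S1
            best = (sse, float(S1), per)
    sse, S1, per = best

    weights = np.array([n for _, n in per.values()], dtype=float)
    k1s = np.array([c[0] for c, _ in per.values()])
    k2s = np.array([c[0] + c[1] for c, _ in per.values()])
    kF1 = float(np.average(k1s, weights=weights))
    kF2 = float(np.average(k2s, weights=weights))
    no_break = (
        kF2 - kF1 <= 1e-12
        or S1 >= candidates[-1] - 1e-12
        or S1 <= candidates[0] + 1e-12
    )
    result = FitResult(
        params={"kF1": kF1, "kF2": kF2, "S1": S1},
        objective=sse, n_obs=S.size,
        message="no break detected" if no_break else "",
        extras={"n_below_break": int((S <= S1).sum()),
                "n_groups": len(per)},
    )
    if groups is not None and len(per) >= 2:
        result.random_effects = {
            "kF1": {str(g): float(c[0] - kF1) for g, (c, _) in per.items()},
            "kF2": {str(g): float(c[0] + c[1] - kF2) for g, (c, _) in per.items()},
        }
        result.finalize_sres()
    return result


# ---------------------------------------------------------------------------
# inverse calibration of E_S, gamma(s), a_N via the resting-form equation
# ---------------------------------------------------------------------------


def _maintenance_stub(sex: str, theta: dict, W_mat: float, W_0: float,
                      a_R: float, b_R: float, E_M: float) -> MGMParams:
    """Assemble a minimal valid parameter set for resting-form integration.

    Ingestion and feeding-cost fields are placeholders — the resting form
    never evaluates them.
    """
    kw = (
        {"gamma_B": theta["gamma_B"]}
        if sex == "male"
        else {"gamma_BS": theta["gamma_BS"], "gamma_BR": theta["gamma_BR"]}
    )
    return MGMParams(
        sex=sex, e=0.9, E_M=E_M, E_S=theta["E_S"], alpha=1.0, beta=1.0,
        k=0.0, W_star=2 * W_mat, W_mat=W_mat, S1=0.0, kF1=0.0, kF2=0.0,
        a_N=theta["a_N"], a_R=a_R, b_R=b_R, W_0=W_0, **kw,
    )


def _predict_mass(p: MGMParams, ages: np.ndarray, rtol: float = 1e-7) -> np.ndarray:
    def rhs(t, y):
        W = max(y[0], 1e-9)
        return [(p.a_R * W**p.b_R - maintenance_cost(W, p).R_M) / p.E_S]

    sol = solve_ivp(
        rhs, (float(ages[0]), float(ages[-1])), [p.W_0], t_eval=ages,
        method="LSODA", rtol=rtol, atol=1e-9,
    )
    if not sol.success or sol.y.shape[1] != ages.size:
        raise RuntimeError(f"trial integration failed: {sol.message}")
    return sol.y[0]


def _inverse_single(
    sex: str, ages: np.ndarray, W_obs: np.ndarray, W_mat: float, W_0: float,
    a_R: float, b_R: float, E_M: float, x0_list: list[np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, float, bool]:
    names = (
        ["E_S", "gamma_B", "a_N"] if sex == "male"
        else ["E_S", "gamma_BS", "gamma_BR", "a_N"]
    )

    def resid(x):
        theta = dict(zip(names, x))
        try:
            p = _maintenance_stub(sex, theta, W_mat, W_0, a_R, b_R, E_M)
            return _predict_mass(p, ages) - W_obs
        except (ParameterError, ValidityDomainError, RuntimeError):
            return np.full(ages.size, 1e6)  # rejected trial, large penalty

    best = None
    for x0 in x0_list:
        try:
            res = least_squares(resid, x0, bounds=bounds, x_scale=np.maximum(np.abs(x0), 1e-6))
        except Exception:  # pragma: no cover
            continue
        if (
            best is None
            or res.cost < best.cost * (1 - 1e-9)
            or (abs(res.cost - best.cost) <= 1e-9 * best.cost and res.x[-1] < best.x[-1])
        ):
            best = res
    if best is None:
        raise RuntimeError("all inverse-optimization starts failed")
    return best.x, float(2 * best.cost), bool(best.success)


def _profile_W_mat(
    sex, ages, W_obs, W_mat0, W_0, a_R, b_R, E_M, x_warm, bounds,
    sse0, ok0, span: float = 0.08, n_cand: int = 5
):
    """Refine a female maturity mass by profiling the fit objective."""
    best = (sse0, W_mat0, x_warm, ok0)
    for f in np.linspace(1.0 - span, 1.0 + span, n_cand):
        if abs(f - 1.0) < 1e-12:
            continue
        try:
            x, sse, ok = _inverse_single(
                sex, ages, W_obs, W_mat0 * f, W_0, a_R, b_R, E_M,
                [np.asarray(x_warm)], bounds,
            )
        except RuntimeError:
            continue
        if sse < best[0]:
            best = (sse, W_mat0 * f, x, ok)
    sse, W_mat, x, ok = best
    return W_mat, x, sse, ok


def fit_inverse_growth(
    series: list[ProcessedSeries],
    a_R: float,
    b_R: float,
    sex: str,
    E_M: float = 6.0,
    n_starts: int = 16,
    seed: int = 0,
    per_individual: bool = True,
    profile_W_mat: bool = True,
) -> FitResult:
    """Inverse calibration of the maintenance/overhead parameter group.

    Stage 1 fits the sex-averaged mass curve with multi-start bounded
    least squares (Latin-hypercube starts, fixed seed; ties broken toward
    smaller a_N).  Stage 2 refits each individual from the stage-1
    optimum.  When per-individual refits are run, the reported fixed
    effects are the means of the individual estimates (the classical
    two-stage estimator — the average of a nonlinear model's solutions is
    not itself a solution, so the averaged-curve fit alone is biased when
    individuals vary); the averaged-curve optimum is kept in
    ``extras['stage1_params']``.  Per-individual deviations from the
    fixed effects are the random effects whose spread yields SREs.
    Trial parameter sets that leave the validity domain are rejected with
    a penalty.
    """
    group = [s for s in series if s.sex == sex]
    if not group:
        raise ValueError(f"no individuals of sex {sex!r}")
    avg = sex_average(group)[sex]
    # raw (unsmoothed) masses: cross-individual averaging is the noise
    # control here, and the truncated moving-average windows would bias the
    # curve ends
    col = "W_raw_mg" if "W_raw_mg" in avg.columns else "W_mg"
    occ = avg[np.isfinite(avg[col])]
    ages = occ["age_d"].to_numpy(dtype=float)
    W_obs = occ[col].to_numpy(dtype=float)
    W_mat = avg.attrs.get("maturity_mass") or float(W_obs.max())
    W_0 = float(W_obs[0])
    W_max = float(W_obs.max())

    names = (
        ["E_S", "gamma_B", "a_N"] if sex == "male"
        else ["E_S", "gamma_BS", "gamma_BR", "a_N"]
    )
    gamma_hi = a_R * W_mat ** (b_R - 1.0)
    lo = np.array([1e-3] + [1e-5] * (len(names) - 2) + [0.0])
    hi = np.array([10.0 * E_M] + [gamma_hi] * (len(names) - 2) + [0.9 / W_max])

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    x0_list = [lo + u * (hi - lo) for u in sampler.random(n_starts)]
    x0_list = [np.clip(x, lo + 1e-9, hi - 1e-12) for x in x0_list]

    x_fe, sse, ok = _inverse_single(
        sex, ages, W_obs, W_mat, W_0, a_R, b_R, E_M, x0_list, (lo, hi)
    )
    if sex == "female" and profile_W_mat:
        # the imago flag only brackets maturity to one occasion interval;
        # the growth-curve kink at W_mat identifies it more sharply, so
        # profile W_mat around the interval-midpoint estimate (warm starts)
        W_mat, x_fe, sse, ok = _profile_W_mat(
            sex, ages, W_obs, W_mat, W_0, a_R, b_R, E_M, x_fe, (lo, hi), sse, ok
        )
    result = FitResult(
        params=dict(zip(names, map(float, x_fe))),
        objective=sse, converged=ok, n_obs=ages.size,
        message="" if ok else "stage-1 optimizer did not converge; best incumbent reported",
        extras={"W_mat": W_mat, "W_0": W_0, "sex": sex},
    )
    if per_individual:
        estimates: dict[str, dict[str, float]] = {name: {} for name in names}
        for s in group:
            ind_Wm = s.maturity_mass if s.maturity_mass is not None else W_mat
            W_i = s.W_raw if s.W_raw.size else s.W
            try:
                x_i, sse_i, ok_i = _inverse_single(
                    sex, s.ages, W_i, ind_Wm, float(W_i[0]), a_R, b_R, E_M,
                    [x_fe], (lo, hi),
                )
                if sex == "female" and profile_W_mat:
                    _, x_i, sse_i, ok_i = _profile_W_mat(
                        sex, s.ages, W_i, ind_Wm, float(W_i[0]), a_R, b_R,
                        E_M, x_i, (lo, hi), sse_i, ok_i, n_cand=3,
                    )
            except RuntimeError:
                log.warning("individual refit failed for %s", s.id)
                continue
            for name, v_i in zip(names, x_i):
                estimates[name][s.id] = float(v_i)
        if next(iter(estimates.values()), None):
            result.extras["stage1_params"] = dict(result.params)
            result.params = {
                name: float(np.mean(list(vals.values())))
                for name, vals in estimates.items()
            }
            result.random_effects = {
                name: {i: v - result.params[name] for i, v in vals.items()}
                for name, vals in estimates.items()
            }
            result.finalize_sres()
    return result
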