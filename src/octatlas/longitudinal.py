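"""Longitudinal analysis: central-area summaries, LOESS trajectories and
the joint growth-curve / proportional-hazards model.

The central feature value of an eye at a visit is the mean over the
central foveal disc (3 mm diameter) of its atlas-space map.  Feature
development is modelled as a linear growth-curve mixed model

    y_ij = (b̄0 + g0[grp] + b0_i) + (b̄1 + g1[grp] + b1_i) · t_ij + e_ij

with dummy-coded groups (non-progressors as reference) and per-eye
random intercept/slope.  Right-censored conversion is handled by a
proportional-hazards submodel sharing the random effects:

    h_i(t) = h0g(t) · exp(a0·b0_i + a1·b1_i)

with a piecewise-constant baseline h0g over 6-month intervals,
stratified by group (non-progressors' stratum simply estimates a
negligible rate, since the label is defined by not converting).  Inference
is Bayesian MCMC: conjugate Gibbs updates for the longitudinal
parameters, a gamma update for the baseline hazard, an independence
Metropolis step for the random effects (proposing from their
longitudinal full conditional) and a random-walk step for the
association coefficients.  Convergence is gated on split R-hat across
chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import EnfaceMap

__all__ = [
    "MCMCConfig",
    "ParamSummary",
    "JointModelFit",
    "MixedModelFit",
    "LoessFit",
    "central_mean",
    "loess_trajectory",
    "mixed_model_only",
    "fit_joint_model",
]

FIXED_NAMES = (
    "intercept",
    "intercept_MNV",
    "intercept_MA",
    "slope",
    "slope_MNV",
    "slope_MA",
)


# --------------------------------------------------------------------------
# central-area summary
# --------------------------------------------------------------------------

def central_mean(enface: EnfaceMap, diameter_mm: float = 3.0) -> float:
    """Mean over valid pixels within the central foveal disc.

    Eccentricity is measured from the map's physical origin frame centre
    (0, 0) — the fovea for atlas-space maps.  Returns NaN when no valid
    central pixel exists.
    """
    x, y = enface.grid.coordinate_arrays()
    sel = (np.hypot(x, y) <= diameter_mm / 2.0) & enface.valid_mask
    sel &= np.isfinite(enface.values)
    if not sel.any():
        return float("nan")
    return float(enface.values[sel].mean())


# --------------------------------------------------------------------------
# LOESS
# --------------------------------------------------------------------------

@dataclass
class LoessFit:
    grid: np.ndarray
    fitted: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    span: float


def loess_trajectory(
    records: pd.DataFrame,
    time_axis: str = "in-study",
    conversion_times: dict | None = None,
    span: float = 0.75,
    n_grid: int = 50,
) -> LoessFit:
    """Local-linear LOESS of feature value over time, with 0.95 CI.

    ``records`` needs columns eye_id, month, value (one feature).  With
    ``time_axis='to-conversion'`` each eye's months are shifted by its
    conversion time (from ``conversion_times``) so the grid ends at 0;
    with ``'in-study'`` months since baseline are used.  The CI comes
    from the pointwise standard error of the linear smoother.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records for a LOESS fit")
    t = records["month"].to_numpy(dtype=float)
    y = records["value"].to_numpy(dtype=float)
    if time_axis == "to-conversion":
        if conversion_times is None:
            raise ValueError("conversion_times required for the to-conversion axis")
        t = t - records["eye_id"].map(conversion_times).to_numpy(dtype=float)
        grid = np.linspace(t.min(), 0.0, n_grid)
    elif time_axis == "in-study":
        grid = np.linspace(t.min(), t.max(), n_grid)
    else:
        raise ValueError("time_axis must be 'in-study' or 'to-conversion'")

    n = len(t)
    k = max(int(np.ceil(span * n)), 3)
    if k > n:
        raise ValueError("span window larger than the data")
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    fitted = np.empty(n_grid)
    se = np.empty(n_grid)
    resid_var = None
    # first pass: residual variance from fits at the data points
    fit_at_data = np.array([_local_linear(ts, ys, x0, k)[0] for x0 in ts])
    dof = max(n - 2, 1)
    resid_var = float(((ys - fit_at_data) ** 2).sum() / dof)
    for i, x0 in enumerate(grid):
        yhat, l2 = _local_linear(ts, ys, x0, k)
        fitted[i] = yhat
        se[i] = np.sqrt(resid_var * l2)
    return LoessFit(grid=grid, fitted=fitted, ci_lo=fitted - 1.96 * se, ci_hi=fitted + 1.96 * se, span=span)


def _local_linear(ts, ys, x0, k):
    """Tricube-weighted degree-1 fit at x0; returns (ŷ, ||l(x0)||²)."""
    d = np.abs(ts - x0)
    h = np.partition(d, k - 1)[k - 1]
    h = max(h, 1e-12)
    w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
    sw = w.sum()
    X = np.column_stack([np.ones_like(ts), ts - x0])
    WX = X * w[:, None]
    A = X.T @ WX
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return float(np.average(ys, weights=w)), float((w**2).sum() / sw**2)
    l = (Ainv @ WX.T)[0]  # weights producing the intercept = fit at x0
    return float(l @ ys), float((l**2).sum())


# --------------------------------------------------------------------------
# mixed model (no survival linkage)
# --------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    fixed_effects: dict
    cov_re: np.ndarray
    residual_sd: float
    converged: bool
    result: object = None


def _design(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fixed design (dummy-coded groups, reference NONP) + random design."""
    grp = records["group"].to_numpy()
    t = records["month"].to_numpy(dtype=float)
    mnv = (grp == "MNV").astype(float)
    ma = (grp == "MA").astype(float)
    X = np.column_stack([np.ones_like(t), mnv, ma, t, mnv * t, ma * t])
    Z = np.column_stack([np.ones_like(t), t])
    y = records["value"].to_numpy(dtype=float)
    return X, Z, y, t


def mixed_model_only(records: pd.DataFrame) -> MixedModelFit:
    """Maximum-likelihood growth-curve fit (random intercept + slope).

    Serves as initialization for, and zero-association cross-check of,
    the joint model.  A singular random-effects covariance triggers a
    fall-back to a random intercept only, with a warning.
    """
    import statsmodels.formula.api as smf

    if records["eye_id"].nunique() < 2:
        raise ValueError("random effects are unidentifiable with a single eye")
    df = records.copy()
    formula = "value ~ C(group, Treatment('NONP')) * month" if df[
        "group"
    ].nunique() > 1 else "value ~ month"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["eye_id"], re_formula="~month")
        try:
            res = model.fit(reml=True, method="lbfgs")
            singular = not np.all(np.linalg.eigvalsh(res.cov_re.to_numpy()) > 1e-10)
        except (np.linalg.LinAlgError, ValueError):
            res, singular = None, True
        if res is None or singular:
            warnings.warn("singular random-effects covariance; falling back to "
                          "a random intercept only", stacklevel=2)
            model = smf.mixedlm(formula, df, groups=df["eye_id"], re_formula="~1")
            res = model.fit(reml=True, method="lbfgs")
    fe = _map_fixed_names(res.fe_params.to_dict(), df["group"].nunique() > 1)
    cov_re = res.cov_re.to_numpy() * res.scale
    return MixedModelFit(
        fixed_effects=fe,
        cov_re=cov_re,
        residual_sd=float(np.sqrt(res.scale)),
        converged=bool(res.converged),
        result=res,
    )


def _map_fixed_names(params: dict, multi_group: bool) -> dict:
    if not multi_group:
        return {"intercept": params.get("Intercept", np.nan), "slope": params.get("month", np.nan)}
    out = {}
    for key, val in params.items():
        name = key
        name = name.replace("C(group, Treatment('NONP'))[T.", "").replace("]", "")
        if name == "Intercept":
            out["intercept"] = val
        elif name == "month":
            out["slope"] = val
        elif name in ("MNV", "MA"):
            out[f"intercept_{name}"] = val
        elif name.endswith(":month"):
            out[f"slope_{name[:-6]}"] = val
    return out


# --------------------------------------------------------------------------
# joint model
# --------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    n_chains: int = 4
    n_iter: int = 5000
    n_warmup: int = 2000
    seed: int = 0
    rhat_threshold: float = 1.1


@dataclass
class ParamSummary:
    mean: float
    sd: float
    ci_lo: float
    ci_hi: float
    tail_prob: float  # 2*min(P(>0), P(<0)); Bayesian analogue of a p-value
    rhat: float


@dataclass
class JointModelFit:
    fixed_effects: dict  # name -> ParamSummary
    random_effect_sd: tuple
    random_effect_corr: float
    residual_sd: float
    hazard_rates: list
    association: list  # [ParamSummary, ParamSummary]
    converged: bool
    rhat: dict = field(default_factory=dict)
    accept_rate_alpha: float = float("nan")


def fit_joint_model(
    records: pd.DataFrame,
    survival: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    hazard_breaks: tuple = (0.0, 6.0, 12.0, 18.0, 24.0),
) -> JointModelFit:
    """Bayesian joint fit of the growth-curve and hazard submodels.

    ``records``: eye_id, group, month, value (one feature);
    ``survival``: eye_id, time, event.  Every survival eye must have at
    least one longitudinal record.  Non-convergence (split R-hat above
    threshold for any reported parameter) flags the fit; summaries are
    still returned.
    """
    if mcmc is None:
        mcmc = MCMCConfig()
    eyes = survival["eye_id"].to_numpy()
    if not set(eyes) <= set(records["eye_id"]):
        raise ValueError("every survival eye needs at least one longitudinal record")
    records = records[records["eye_id"].isin(set(eyes))].reset_index(drop=True)
    eye_index = {e: i for i, e in enumerate(eyes)}
    idx = records["eye_id"].map(eye_index).to_numpy()
    X, Z, y, t = _design(records)
    n_eye = len(eyes)
    times = survival["time"].to_numpy(dtype=float)
    events = survival["event"].to_numpy(dtype=bool)
    # baseline hazard stratified by group (label defined by conversion fate)
    eye_group = (
        records.drop_duplicates("eye_id").set_index("eye_id")["group"].reindex(eyes).to_numpy()
    )
    strata_labels = sorted(set(eye_group))
    strat = np.array([strata_labels.index(g) for g in eye_group])
    breaks = np.asarray(hazard_breaks, dtype=float)
    K = len(breaks) - 1
    # exposure of each eye in each interval, and event-interval index
    expo = np.clip(times[:, None], None, breaks[1:][None, :]) - breaks[:-1][None, :]
    expo = np.clip(expo, 0.0, None)
    ev_k = np.clip(np.searchsorted(breaks, times, side="right") - 1, 0, K - 1)

    # per-eye sufficient statistics for the random-effect conditional
    ZtZ = np.zeros((n_eye, 2, 2))
    np.add.at(ZtZ, idx, Z[:, :, None] * Z[:, None, :])

    chains = []
    ss = np.random.SeedSequence(mcmc.seed)
    for chain_seed in ss.spawn(mcmc.n_chains):
        chains.append(
            _run_chain(
                chain_seed, mcmc, X, Z, y, idx, n_eye, ZtZ, expo, ev_k, events, K,
                strat, eye_group,
            )
        )
    return _summarize(chains, mcmc, strata_labels)


# per-group adjustment directions in the fixed-effect vector for the
# recentering (interweaving) move: shifting a group's mean intercept or
# slope between the fixed effects and its eyes' random effects
_ADJ_INT = {
    "NONP": np.array([1.0, -1.0, -1.0, 0, 0, 0]),
    "MNV": np.array([0, 1.0, 0, 0, 0, 0]),
    "MA": np.array([0, 0, 1.0, 0, 0, 0]),
}
_ADJ_SLOPE = {
    "NONP": np.array([0, 0, 0, 1.0, -1.0, -1.0]),
    "MNV": np.array([0, 0, 0, 0, 1.0, 0]),
    "MA": np.array([0, 0, 0, 0, 0, 1.0]),
}


def _run_chain(seed, mcmc, X, Z, y, idx, n_eye, ZtZ, expo, ev_k, events, K, strat, eye_group):
    rng = np.random.default_rng(seed)
    N, p = X.shape
    XtX = X.T @ X
    n_strata = int(strat.max()) + 1
    group_members = {g: np.nonzero(eye_group == g)[0] for g in set(eye_group)}

    # initial values from least squares, overdispersed starts
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    beta += rng.normal(0, 0.1, size=p)
    resid = y - X @ beta
    sigma2 = max(float(resid.var()), 1e-6)
    Sigma_b = np.diag([max(sigma2, 1.0), 0.01])
    b = np.zeros((n_eye, 2))
    lam = np.full((n_strata, K), 0.02)
    alpha = np.zeros(2)
    prop_sd = np.array([0.02, 1.0])
    nu0, Psi0 = 4.0, np.diag([1.0, 0.001])
    a_sig, b_sig = 0.01, 0.01
    a_lam, b_lam = 0.01, 0.01

    n_keep = mcmc.n_iter - mcmc.n_warmup
    draws = {
        "beta": np.empty((n_keep, p)),
        "sigma": np.empty(n_keep),
        "sd0": np.empty(n_keep),
        "sd1": np.empty(n_keep),
        "corr": np.empty(n_keep),
        "lam": np.empty((n_keep, n_strata * K)),
        "alpha": np.empty((n_keep, 2)),
    }
    acc_alpha = 0
    n_alpha = 0
    # events per stratum and interval
    d_sk = np.zeros((n_strata, K))
    np.add.at(d_sk, (strat[events], ev_k[events]), 1.0)

    for it in range(mcmc.n_iter):
        zb = b[idx, 0] + b[idx, 1] * Z[:, 1]
        # --- beta | rest (conjugate normal, near-flat prior) ---
        prec = XtX / sigma2 + np.eye(p) * 1e-8
        mean = np.linalg.solve(prec, X.T @ (y - zb) / sigma2)
        beta = mean + np.linalg.cholesky(np.linalg.inv(prec)) @ rng.normal(size=p)
        # --- sigma2 | rest ---
        resid = y - X @ beta - zb
        sigma2 = 1.0 / rng.gamma(a_sig + N / 2.0, 1.0 / (b_sig + 0.5 * (resid**2).sum()))
        # --- Sigma_b | b ---
        S = Psi0 + b.T @ b
        Sigma_b = stats.invwishart.rvs(df=nu0 + n_eye, scale=S, random_state=rng)
        # --- b_i | rest: independence MH from the longitudinal conditional ---
        r = y - X @ beta
        s0 = np.bincount(idx, weights=r, minlength=n_eye)
        s1 = np.bincount(idx, weights=r * Z[:, 1], minlength=n_eye)
        Sb_inv = np.linalg.inv(Sigma_b)
        P = ZtZ / sigma2 + Sb_inv[None, :, :]  # (n, 2, 2)
        det = P[:, 0, 0] * P[:, 1, 1] - P[:, 0, 1] * P[:, 1, 0]
        Vi = np.empty_like(P)
        Vi[:, 0, 0] = P[:, 1, 1] / det
        Vi[:, 1, 1] = P[:, 0, 0] / det
        Vi[:, 0, 1] = Vi[:, 1, 0] = -P[:, 0, 1] / det
        rhs = np.stack([s0, s1], axis=1) / sigma2
        m = np.einsum("nij,nj->ni", Vi, rhs)
        L11 = np.sqrt(Vi[:, 0, 0])
        L21 = Vi[:, 1, 0] / L11
        L22 = np.sqrt(np.maximum(Vi[:, 1, 1] - L21**2, 1e-14))
        eps = rng.normal(size=(n_eye, 2))
        prop = m.copy()
        prop[:, 0] += L11 * eps[:, 0]
        prop[:, 1] += L21 * eps[:, 0] + L22 * eps[:, 1]
        lam_eye = lam[strat]  # (n, K)
        Lam_i = (expo * lam_eye).sum(axis=1)
        lam_ev = lam_eye[np.arange(n_eye), ev_k]
        log_ratio = _surv_loglik(prop, alpha, lam_ev, Lam_i, events) - _surv_loglik(
            b, alpha, lam_ev, Lam_i, events
        )
        accept = np.log(rng.random(n_eye)) < log_ratio
        b[accept] = prop[accept]
        # --- recentering (interweaving): trade group means of b against
        #     the fixed effects; exact for the longitudinal part, MH-
        #     corrected for the survival part ---
        for comp, adj_map in ((0, _ADJ_INT), (1, _ADJ_SLOPE)):
            other = 1 - comp
            cond_slope = Sigma_b[comp, other] / Sigma_b[other, other]
            cond_var = Sigma_b[comp, comp] - cond_slope * Sigma_b[comp, other]
            for g, members in group_members.items():
                ng = len(members)
                resid_b = b[members, comp] - cond_slope * b[members, other]
                delta = rng.normal(resid_b.mean(), np.sqrt(max(cond_var, 1e-12) / ng))
                bb = b[members].copy()
                bb[:, comp] -= delta
                lam_ev_g = lam_ev[members]
                Lam_g = Lam_i[members]
                ev_g = events[members]
                lr = (
                    _surv_loglik(bb, alpha, lam_ev_g, Lam_g, ev_g).sum()
                    - _surv_loglik(b[members], alpha, lam_ev_g, Lam_g, ev_g).sum()
                )
                if np.log(rng.random()) < lr:
                    b[members, comp] -= delta
                    beta = beta + delta * adj_map[g]
        # --- lambda_{g,k} | rest (conjugate gamma per stratum) ---
        eta = np.exp(np.clip(b @ alpha, -30, 30))
        exposure_sk = np.zeros((n_strata, K))
        np.add.at(exposure_sk, strat, expo * eta[:, None])
        lam = rng.gamma(a_lam + d_sk, 1.0 / (b_lam + np.maximum(exposure_sk, 1e-12)))
        lam = np.maximum(lam, 1e-10)
        # --- alpha | rest (random-walk MH) ---
        lam_eye = lam[strat]
        Lam_i = (expo * lam_eye).sum(axis=1)
        cur_ll = _alpha_loglik(b, alpha, Lam_i, events)
        prop_a = alpha + rng.normal(0, prop_sd)
        prop_ll = _alpha_loglik(b, prop_a, Lam_i, events)
        n_alpha += 1
        if np.log(rng.random()) < prop_ll - cur_ll - (prop_a**2).sum() / (2 * 25.0) + (
            alpha**2
        ).sum() / (2 * 25.0):
            alpha = prop_a
            acc_alpha += 1
        if it == mcmc.n_warmup // 2 and n_alpha > 0:
            rate = acc_alpha / n_alpha
            prop_sd *= np.clip(rate / 0.3, 0.3, 3.0)

        if it >= mcmc.n_warmup:
            k = it - mcmc.n_warmup
            draws["beta"][k] = beta
            draws["sigma"][k] = np.sqrt(sigma2)
            draws["sd0"][k] = np.sqrt(Sigma_b[0, 0])
            draws["sd1"][k] = np.sqrt(Sigma_b[1, 1])
            draws["corr"][k] = Sigma_b[0, 1] / np.sqrt(Sigma_b[0, 0] * Sigma_b[1, 1])
            draws["lam"][k] = lam.ravel()
            draws["alpha"][k] = alpha
    draws["accept_rate_alpha"] = acc_alpha / max(n_alpha, 1)
    return draws


def _surv_loglik(b, alpha, lam_event, Lam_i, events):
    eta = np.clip(b @ alpha, -30, 30)
    ll = -np.exp(eta) * Lam_i
    ll[events] += np.log(lam_event[events]) + eta[events]
    return ll


def _alpha_loglik(b, alpha, Lam_i, events):
    eta = np.clip(b @ alpha, -30, 30)
    return float((eta[events]).sum() - (np.exp(eta) * Lam_i).sum())


def _split_rhat(chains_of_draws: list[np.ndarray]) -> float:
    """Split R-hat of a scalar parameter across chains."""
    halves = []
    for d in chains_of_draws:
        half = len(d) // 2
        if half < 2:
            return float("nan")
        halves.extend([d[:half], d[half : 2 * half]])
    m = len(halves)
    n = len(halves[0])
    means = np.array([h.mean() for h in halves])
    vars_ = np.array([h.var(ddof=1) for h in halves])
    W = vars_.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + B / (n * W)))


def _summarize(chains: list[dict], mcmc: MCMCConfig, strata_labels=None) -> JointModelFit:
    def pooled(key, col=None):
        if col is None:
            return [c[key] for c in chains], np.concatenate([c[key] for c in chains])
        return (
            [c[key][:, col] for c in chains],
            np.concatenate([c[key][:, col] for c in chains]),
        )

    def summarize(per_chain, alldraws):
        lo, hi = np.quantile(alldraws, [0.025, 0.975])
        pg = (alldraws > 0).mean()
        return ParamSummary(
            mean=float(alldraws.mean()),
            sd=float(alldraws.std(ddof=1)),
            ci_lo=float(lo),
            ci_hi=float(hi),
            tail_prob=float(2 * min(pg, 1 - pg)),
            rhat=_split_rhat(per_chain),
        )

    fixed = {}
    rhat = {}
    for j, name in enumerate(FIXED_NAMES):
        per, alld = pooled("beta", j)
        fixed[name] = summarize(per, alld)
        rhat[name] = fixed[name].rhat
    n_lam = chains[0]["lam"].shape[1]
    n_strata = len(strata_labels) if strata_labels else 1
    K = n_lam // n_strata
    hazard = []
    for k in range(n_lam):
        per, alld = pooled("lam", k)
        hazard.append(summarize(per, alld))
        label = strata_labels[k // K] if strata_labels else ""
        rhat[f"lambda_{label}_{k % K}"] = hazard[-1].rhat
    assoc = []
    for j in range(2):
        per, alld = pooled("alpha", j)
        assoc.append(summarize(per, alld))
        rhat[f"alpha_{j}"] = assoc[-1].rhat
    for key in ("sigma", "sd0", "sd1"):
        per, alld = pooled(key)
        rhat[key] = _split_rhat(per)
    sd0 = np.concatenate([c["sd0"] for c in chains]).mean()
    sd1 = np.concatenate([c["sd1"] for c in chains]).mean()
    corr = np.concatenate([c["corr"] for c in chains]).mean()
    sigma = np.concatenate([c["sigma"] for c in chains]).mean()
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(all(v < mcmc.rhat_threshold for v in finite))
    return JointModelFit(
        fixed_effects=fixed,
        random_effect_sd=(float(sd0), float(sd1)),
        random_effect_corr=float(corr),
        residual_sd=float(sigma),
        hazard_rates=hazard,
        association=assoc,
        converged=converged,
        rhat=rhat,
        accept_rate_alpha=float(np.mean([c["accept_rate_alpha"] for c in chains])),
    )
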