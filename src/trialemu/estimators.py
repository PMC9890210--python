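"""Average-treatment-effect estimators for a binary 5-year composite outcome.

Five routes to the ATE of CABG vs complex PCI on the risk-difference scale:

* :func:`biprobit_iv_ate` — the primary analysis: a recursive bivariate
  probit with the regional-preference instrument in the treatment equation
  only, joint MLE over both equations with correlated latent errors, and
  the ATE as the average of ``Phi(beta + theta'x) - Phi(theta'x)``;
* :func:`regression_adjustment_ate` — single-equation probit outcome model
  with G-computation;
* :func:`psm_ate` — within-cohort propensity matching (caliper 0.01, 1:1,
  without replacement) with the matched-sample rate difference;
* :func:`metalearner_ate` — S/T/X meta-learners over a gradient-boosted
  tree base learner;
* :func:`subgroup_ates` — stratified regression-adjustment ATEs with
  likelihood-ratio interaction tests.

Confidence intervals are percentile bootstrap by default (seeded); a
normal-approximation bootstrap variant is available for simulation studies
that need many cheap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import ndtr, owens_t
from scipy.stats import norm

from trialemu._seeds import derive_rng
from trialemu.matching import MatchSpec, nn_match

__all__ = [
    "ATEEstimate",
    "BiprobitFit",
    "bvn_cdf",
    "build_design",
    "biprobit_iv_ate",
    "regression_adjustment_ate",
    "psm_ate",
    "metalearner_ate",
    "subgroup_ates",
]

def fit_discrete(model, maxiter: int = 200):
    """Fit a statsmodels Logit/Probit, falling back to BFGS when the Newton
    Hessian is singular (rare indicator columns in small samples)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(disp=0, maxiter=maxiter)
    except np.linalg.LinAlgError:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(disp=0, maxiter=max(maxiter, 500), method="bfgs")


DEFAULT_COVARIATES = [
    "age",
    "male",
    "ethnicity",
    "imd",
    "diabetes",
    "hypertension",
    "lipidaemia",
    "ckd",
    "prior_stroke",
    "prior_mi",
]


# ---------------------------------------------------------------------------
# bivariate normal CDF (Owen's T identity)
# ---------------------------------------------------------------------------

def bvn_cdf(a, b, rho):
    """P(U <= a, V <= b) for standard bivariate normal with correlation rho.

    Vectorised; uses Owen's T function, accurate to well below 1e-8 over the
    admissible range. ``rho`` exactly +/-1 falls back to the comonotone /
    antitone closed forms; ``|rho| > 1`` raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1.0):
        raise ValueError("|rho| must be <= 1")
    a, b, rho = np.broadcast_arrays(a, b, rho)
    out = np.empty(a.shape, dtype=float)

    hi = rho >= 1.0 - 1e-10
    lo = rho <= -1.0 + 1e-10
    mid = ~(hi | lo)
    if hi.any():
        out[hi] = np.minimum(ndtr(a[hi]), ndtr(b[hi]))
    if lo.any():
        out[lo] = np.maximum(ndtr(a[lo]) + ndtr(b[lo]) - 1.0, 0.0)
    if mid.any():
        out[mid] = _bvn_owen(a[mid], b[mid], rho[mid])
    return out if out.shape else float(out)


def _bvn_owen(h, k, rho):
    # infinities: marginalize / zero out
    h = np.where(np.isposinf(h), 1e10, h)
    k = np.where(np.isposinf(k), 1e10, k)
    neg = np.isneginf(h) | np.isneginf(k)
    h = np.where(neg, 0.0, h)
    k = np.where(neg, 0.0, k)
    # substitute an epsilon for exact zeros; the formula is continuous and
    # the perturbation error is O(1e-12)
    hs = np.where(h == 0.0, 1e-12, h)
    ks = np.where(k == 0.0, 1e-12, k)
    s = np.sqrt(1.0 - rho * rho)
    a1 = (ks - rho * hs) / (hs * s)
    a2 = (hs - rho * ks) / (ks * s)
    res = 0.5 * (ndtr(hs) + ndtr(ks)) - owens_t(hs, a1) - owens_t(ks, a2)
    res = res - np.where(hs * ks < 0.0, 0.5, 0.0)
    res = np.where(neg, 0.0, res)
    return np.clip(res, 0.0, 1.0)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ATEEstimate:
    estimator: str
    ate: float
    ci_low: float
    ci_high: float
    ci_method: str
    n: int
    seed: int | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 <= self.ate <= 1.0:
            raise ValueError("ATE must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "ate": self.ate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "n": self.n,
            "seed": self.seed,
            "notes": self.notes,
        }


@dataclass
class BiprobitFit:
    treat_names: list
    treat_coefs: np.ndarray
    outcome_names: list
    outcome_coefs: np.ndarray
    rho: float
    loglik: float
    converged: bool
    n: int


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    cohort: pd.DataFrame, covariates: list[str] | None = None, standardize: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Numeric covariate design (no intercept) from a cohort table.

    Continuous columns are standardized (for optimizer conditioning),
    categorical ethnicity enters as indicator contrasts against its largest
    observed level (a missing/NA level is retained as its own category), and
    rows with missing values in any used column are dropped. Returns the
    design and the surviving cohort rows.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    cols = {}
    data = cohort.copy()
    for cov in covariates:
        if cov == "ethnicity":
            levels = data["ethnicity"].astype(str)
            ref = levels.value_counts().idxmax()
            for lev in sorted(levels.unique()):
                if lev != ref:
                    cols[f"ethnicity_{lev}"] = (levels == lev).astype(float)
        elif cov == "sex":
            cols["male"] = (data["sex"].astype(str) == "M").astype(float)
        else:
            cols[cov] = pd.to_numeric(data[cov], errors="coerce")
    X = pd.DataFrame(cols, index=data.index)
    keep = X.notna().all(axis=1)
    X = X.loc[keep]
    # degenerate columns (constant, or binary with <3 minority cases) would
    # make the probit Hessians singular or quasi-separable in small strata
    for c in list(X.columns):
        col = X[c]
        if col.nunique() < 2:
            X = X.drop(columns=c)
        elif set(col.unique()) <= {0.0, 1.0} and min(col.sum(), (1 - col).sum()) < 3:
            X = X.drop(columns=c)
    if standardize:
        for c in X.columns:
            col = X[c]
            if col.nunique() > 2:
                sd = col.std(ddof=1)
                X[c] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    return X, cohort.loc[X.index]


# ---------------------------------------------------------------------------
# recursive bivariate probit
# ---------------------------------------------------------------------------

def _biprobit_nll_grad(params, Xt, Xy_base, t, y):
    """Mean negative log-likelihood and gradient.

    Treatment equation: T* = Xt @ bt + u.  Outcome: Y* = beta*T + Xy @ by + v,
    corr(u, v) = rho = tanh(z). Likelihood per observation with sign flips
    q_t = 2t-1, q_y = 2y-1 is Phi2(q_y*wy, q_t*wt, q_y*q_t*rho).
    """
    kt = Xt.shape[1]
    ky = Xy_base.shape[1]
    bt = params[:kt]
    by = params[kt : kt + ky]
    z = params[-1]
    rho = np.tanh(z)
    n = len(t)

    wt = Xt @ bt
    wy = Xy_base @ by  # Xy_base includes the treatment column
    qt = 2.0 * t - 1.0
    qy = 2.0 * y - 1.0
    aa = qy * wy
    bb = qt * wt
    rr = qy * qt * rho

    s2 = 1.0 - rr * rr
    s = np.sqrt(s2)
    P = np.maximum(_bvn_owen(aa, bb, rr), 1e-300)
    nll = -np.log(P).mean()

    phi_a = norm.pdf(aa)
    phi_b = norm.pdf(bb)
    ga = phi_a * ndtr((bb - rr * aa) / s) / P
    gb = phi_b * ndtr((aa - rr * bb) / s) / P
    phi2 = np.exp(-(aa * aa - 2.0 * rr * aa * bb + bb * bb) / (2.0 * s2)) / (2.0 * np.pi * s)
    gr = phi2 / P

    grad = np.empty_like(params)
    grad[:kt] = -(Xt.T @ (gb * qt)) / n
    grad[kt : kt + ky] = -(Xy_base.T @ (ga * qy)) / n
    grad[-1] = -np.sum(gr * qy * qt) / n * (1.0 - rho * rho)
    return nll, grad


def _fit_biprobit(Xt, Xy, t, y, starts=3, gtol=1e-7):
    """Multi-start BFGS MLE; returns (params, loglik, converged)."""
    # starting values from separate single-equation probits
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bt0 = fit_discrete(sm.Probit(t, Xt), maxiter=100).params
        by0 = fit_discrete(sm.Probit(y, Xy), maxiter=100).params
    base = np.concatenate([np.asarray(bt0), np.asarray(by0), [0.0]])
    rho_starts = [0.0, 0.4, -0.4][:starts]
    best = None
    for r0 in rho_starts:
        p0 = base.copy()
        p0[-1] = np.arctanh(r0) if abs(r0) < 1 else 0.0
        res = optimize.minimize(
            _biprobit_nll_grad,
            p0,
            args=(Xt, Xy, t, y),
            jac=True,
            method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        grad_ok = np.linalg.norm(res.jac) < 1e-4
        if best is None or res.fun < best[0].fun:
            best = (res, res.success or grad_ok)
    res, converged = best
    n = len(t)
    return res.x, -res.fun * n, bool(converged)


def _biprobit_ate(params, Xy_cov, ky_cov):
    """G-computed ATE from the outcome equation: mean Phi(c+b+th'x)-Phi(c+th'x)."""
    kt = params.shape[0] - 1 - (ky_cov + 2)  # treat block length
    by = params[kt : kt + ky_cov + 2]
    const, beta = by[0], by[1]
    lin = Xy_cov @ by[2:] + const
    return float(np.mean(ndtr(lin + beta) - ndtr(lin)))


def biprobit_iv_ate(
    cohort: pd.DataFrame,
    instrument_col: str = "instrument",
    covariates: list[str] | None = None,
    outcome_col: str = "composite_event",
    bootstrap: int = 500,
    seed: int = 0,
    ci_method: str = "bootstrap_percentile",
    starts: int = 3,
) -> tuple[ATEEstimate, BiprobitFit]:
    """Instrumental-variable ATE via recursive bivariate probit MLE.

    The instrument enters the treatment equation only; both equations share
    the prespecified covariates; the latent error correlation ``rho``
    absorbs unmeasured confounding. ATE on the risk-difference scale by
    averaging the outcome-equation counterfactual probabilities.
    """
    X, data = build_design(cohort, covariates)
    zcol = pd.to_numeric(data[instrument_col], errors="coerce")
    keep = zcol.notna()
    X, data, zcol = X.loc[keep], data.loc[keep], zcol.loc[keep]
    if zcol.nunique() <= 1:
        raise ValueError("instrument is constant: no regional variation to exploit")
    t = data["treatment"].to_numpy(dtype=float)
    y = data[outcome_col].to_numpy(dtype=float)
    Xc = X.to_numpy(dtype=float)
    z = (zcol - zcol.mean()) / zcol.std(ddof=1)
    n = len(t)

    Xt = np.column_stack([np.ones(n), z.to_numpy(dtype=float), Xc])
    Xy = np.column_stack([np.ones(n), t, Xc])

    params, llf, converged = _fit_biprobit(Xt, Xy, t, y, starts=starts)
    if not converged:
        raise RuntimeError("bivariate probit did not converge; inspect the optimizer trace")
    rho = float(np.tanh(params[-1]))
    ate = _biprobit_ate(params, Xc, Xc.shape[1])

    rng = derive_rng(seed, "biprobit_boot")
    boot = []
    for _ in range(int(bootstrap)):
        idx = rng.integers(0, n, size=n)
        try:
            p_b, _, _ = _fit_biprobit(Xt[idx], Xy[idx], t[idx], y[idx], starts=1)
            boot.append(_biprobit_ate(p_b, Xc[idx], Xc.shape[1]))
        except Exception:
            continue
    ci_low, ci_high, used = _bootstrap_ci(ate, boot, ci_method)

    notes = {"rho": rho, "n_boot_ok": len(boot)}
    if abs(rho) > 0.99:
        notes["warning"] = "rho at boundary"
    est = ATEEstimate("IV_BIPROBIT", ate, ci_low, ci_high, used, n, seed, notes)
    fit = BiprobitFit(
        ["const", instrument_col, *X.columns],
        params[: 2 + Xc.shape[1]],
        ["const", "treatment", *X.columns],
        params[2 + Xc.shape[1] : -1],
        rho,
        llf,
        converged,
        n,
    )
    return est, fit


def _bootstrap_ci(point, boot, ci_method):
    if len(boot) < 10:
        return float("nan"), float("nan"), f"{ci_method} (failed)"
    boot = np.asarray(boot)
    if ci_method == "bootstrap_normal":
        se = boot.std(ddof=1)
        lo, hi = point - 1.959964 * se, point + 1.959964 * se
    else:
        lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(min(lo, point)), float(max(hi, point)), ci_method


# ---------------------------------------------------------------------------
# probit regression adjustment (G-computation)
# ---------------------------------------------------------------------------

def _gcomp_probit(Xc, t, y):
    n = len(t)
    Xy = np.column_stack([np.ones(n), t, Xc])
    res = fit_discrete(sm.Probit(y, Xy))
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("probit outcome model failed (possible separation)")
    b = np.asarray(res.params)
    lin = b[0] + Xc @ b[2:]
    return float(np.mean(ndtr(lin + b[1]) - ndtr(lin)))


def regression_adjustment_ate(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome_col: str = "composite_event",
    bootstrap: int = 500,
    seed: int = 0,
    ci_method: str = "bootstrap_percentile",
) -> ATEEstimate:
    """Multivariable-probit ATE by G-computation over the whole cohort."""
    X, data = build_design(cohort, covariates)
    t = data["treatment"].to_numpy(dtype=float)
    y = data[outcome_col].to_numpy(dtype=float)
    Xc = X.to_numpy(dtype=float)
    n = len(t)
    ate = _gcomp_probit(Xc, t, y)
    rng = derive_rng(seed, "regadj_boot")
    boot = []
    for _ in range(int(bootstrap)):
        idx = rng.integers(0, n, size=n)
        try:
            boot.append(_gcomp_probit(Xc[idx], t[idx], y[idx]))
        except Exception:
            continue
    lo, hi, used = _bootstrap_ci(ate, boot, ci_method)
    return ATEEstimate("REG_ADJUST", ate, lo, hi, used, n, seed)


# ---------------------------------------------------------------------------
# within-cohort propensity-score matching
# ---------------------------------------------------------------------------

def _psm_once(scores, t, y, caliper, order_seed):
    treated = pd.Series(scores[t == 1], index=np.flatnonzero(t == 1))
    control = pd.Series(scores[t == 0], index=np.flatnonzero(t == 0))
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("both arms must be non-empty for matching")
    # claimants = smaller arm, candidates = larger (maximizes pair count)
    if len(treated) <= len(control):
        pairs = nn_match(treated, control, MatchSpec(caliper=caliper, order_seed=order_seed))
        ti, ci = pairs["claimant_id"].to_numpy(), pairs["candidate_id"].to_numpy()
    else:
        pairs = nn_match(control, treated, MatchSpec(caliper=caliper, order_seed=order_seed))
        ti, ci = pairs["candidate_id"].to_numpy(), pairs["claimant_id"].to_numpy()
    if len(pairs) == 0:
        raise RuntimeError("no matches within the caliper")
    return float(y[ti].mean() - y[ci].mean()), len(pairs)


def psm_ate(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome_col: str = "composite_event",
    caliper: float = 0.01,
    bootstrap: int = 200,
    seed: int = 0,
    ci_method: str = "bootstrap_percentile",
    link: str = "probit",
) -> ATEEstimate:
    """Matched-sample rate difference after within-cohort propensity matching.

    Probit propensity model of treatment on the covariates, greedy 1:1
    nearest-neighbour matching without replacement within the caliper, ATE
    as the matched CABG-minus-PCI outcome-rate difference; the bootstrap
    re-runs the entire match per resample.
    """
    X, data = build_design(cohort, covariates)
    t = data["treatment"].to_numpy(dtype=float)
    y = data[outcome_col].to_numpy(dtype=float)
    Xd = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    model = sm.Probit(t, Xd) if link == "probit" else sm.Logit(t, Xd)
    scores = np.asarray(fit_discrete(model).predict(Xd))
    n = len(t)
    ate, n_pairs = _psm_once(scores, t, y, caliper, seed)
    rng = derive_rng(seed, "psm_boot")
    boot = []
    for bi in range(int(bootstrap)):
        idx = rng.integers(0, n, size=n)
        try:
            m_b = sm.Probit(t[idx], Xd[idx]) if link == "probit" else sm.Logit(t[idx], Xd[idx])
            s_b = np.asarray(fit_discrete(m_b).predict(Xd[idx]))
            boot.append(_psm_once(s_b, t[idx], y[idx], caliper, seed + bi + 1)[0])
        except Exception:
            continue
    lo, hi, used = _bootstrap_ci(ate, boot, ci_method)
    return ATEEstimate(
        "PSM", ate, lo, hi, used, n, seed, {"caliper": caliper, "n_pairs": n_pairs}
    )


# ---------------------------------------------------------------------------
# S / T / X meta-learners
# ---------------------------------------------------------------------------

DEFAULT_BASE_LEARNER = {
    "max_depth": 3,
    "n_estimators": 120,
    "learning_rate": 0.1,
    "subsample": 1.0,
    "n_jobs": 1,
}


def _base_learner(config: dict, seed: int):
    from xgboost import XGBRegressor

    cfg = {**DEFAULT_BASE_LEARNER, **(config or {})}
    return XGBRegressor(random_state=int(seed) % (2**31 - 1), verbosity=0, **cfg)


def _metalearner_once(Xc, t, y, kind, config, seed):
    if t.sum() == 0 or t.sum() == len(t):
        raise ValueError("both arms must be non-empty for a meta-learner")
    if kind == "S":
        model = _base_learner(config, seed)
        model.fit(np.column_stack([Xc, t]), y)
        mu1 = model.predict(np.column_stack([Xc, np.ones(len(t))]))
        mu0 = model.predict(np.column_stack([Xc, np.zeros(len(t))]))
        return float(np.mean(mu1 - mu0))
    X1, y1 = Xc[t == 1], y[t == 1]
    X0, y0 = Xc[t == 0], y[t == 0]
    m1 = _base_learner(config, seed).fit(X1, y1)
    m0 = _base_learner(config, seed + 1).fit(X0, y0)
    if kind == "T":
        return float(np.mean(m1.predict(Xc) - m0.predict(Xc)))
    if kind == "X":
        d1 = y1 - m0.predict(X1)  # imputed effects on the treated
        d0 = m1.predict(X0) - y0  # imputed effects on the controls
        tau1 = _base_learner(config, seed + 2).fit(X1, d1)
        tau0 = _base_learner(config, seed + 3).fit(X0, d0)
        from sklearn.linear_model import LogisticRegression

        g = LogisticRegression(max_iter=1000).fit(Xc, t).predict_proba(Xc)[:, 1]
        tau = g * tau0.predict(Xc) + (1.0 - g) * tau1.predict(Xc)
        return float(np.mean(tau))
    raise ValueError(f"unknown meta-learner kind {kind!r}")


def metalearner_ate(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    kind: str = "X",
    outcome_col: str = "composite_event",
    base_learner_config: dict | None = None,
    bootstrap: int = 50,
    seed: int = 0,
    ci_method: str = "bootstrap_percentile",
) -> ATEEstimate:
    """S-, T- or X-learner ATE with a gradient-boosted tree base learner.

    S: one outcome model on (x, t). T: arm-specific outcome models. X:
    counterfactual-imputed individual effects modelled per arm and blended
    by the propensity score. The bootstrap repeats the whole procedure.
    """
    X, data = build_design(cohort, covariates)
    t = data["treatment"].to_numpy(dtype=float)
    y = data[outcome_col].to_numpy(dtype=float)
    Xc = X.to_numpy(dtype=float)
    n = len(t)
    ate = float(np.clip(_metalearner_once(Xc, t, y, kind, base_learner_config, seed), -1.0, 1.0))
    rng = derive_rng(seed, f"meta_{kind}_boot")
    boot = []
    for bi in range(int(bootstrap)):
        idx = rng.integers(0, n, size=n)
        try:
            boot.append(
                _metalearner_once(Xc[idx], t[idx], y[idx], kind, base_learner_config, seed + 7 * bi)
            )
        except Exception:
            continue
    lo, hi, used = _bootstrap_ci(ate, boot, ci_method)
    cfg = {**DEFAULT_BASE_LEARNER, **(base_learner_config or {})}
    return ATEEstimate(
        f"{kind}_LEARNER", ate, lo, hi, used, n, seed, {"base_learner": cfg}
    )


# ---------------------------------------------------------------------------
# subgroup analysis
# ---------------------------------------------------------------------------

def subgroup_ates(
    cohort: pd.DataFrame,
    strata: list[str],
    covariates: list[str] | None = None,
    outcome_col: str = "composite_event",
    bootstrap: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-stratum regression-adjustment ATEs with interaction p-values.

    For each stratification variable, the ATE is re-estimated within each
    level (single-arm levels are flagged, not estimated) and a pooled probit
    with a treatment-by-stratum interaction is compared to the additive
    model by a likelihood-ratio test.
    """
    from scipy.stats import chi2

    rows = []
    for var in strata:
        adj_covs = [c for c in (covariates or DEFAULT_COVARIATES) if c != var]
        # interaction LR test on the pooled cohort
        X, data = build_design(cohort, adj_covs)
        t = data["treatment"].to_numpy(dtype=float)
        y = data[outcome_col].to_numpy(dtype=float)
        levels = data[var]
        dummies = pd.get_dummies(levels, prefix=var, drop_first=True).astype(float)
        Xc = X.to_numpy(dtype=float)
        base_X = np.column_stack([np.ones(len(t)), t, Xc, dummies.to_numpy()])
        inter = dummies.to_numpy() * t[:, None]
        full_X = np.column_stack([base_X, inter])
        ll0 = fit_discrete(sm.Probit(y, base_X)).llf
        ll1 = fit_discrete(sm.Probit(y, full_X)).llf
        df = inter.shape[1]
        lr = max(0.0, 2.0 * (ll1 - ll0))
        p_inter = float(chi2.sf(lr, df)) if df > 0 else float("nan")

        for lev, grp in cohort.groupby(var, sort=True, dropna=False):
            if grp["treatment"].nunique() < 2:
                rows.append(
                    {
                        "variable": var,
                        "stratum": lev,
                        "n": len(grp),
                        "ate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "flag": "single_arm",
                        "p_interaction": p_inter,
                    }
                )
                continue
            est = regression_adjustment_ate(
                grp, adj_covs, outcome_col, bootstrap=bootstrap, seed=seed,
                ci_method="bootstrap_normal",
            )
            rows.append(
                {
                    "variable": var,
                    "stratum": lev,
                    "n": est.n,
                    "ate": est.ate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "flag": "",
                    "p_interaction": p_inter,
                }
            )
    return pd.DataFrame(rows)
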