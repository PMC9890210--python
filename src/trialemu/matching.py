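"""Propensity-score matching of the target cohort to trial IPD.

The emulated trial cohort is derived by matching the administrative target
cohort to trial individual-patient data (IPD) on key baseline covariates:
a logistic model of IPD membership yields propensity scores, and a greedy
nearest-neighbour algorithm pairs cohort patients to IPD anchors within a
caliper on the propensity scale (default 0.01), 1:1 and without replacement.
The CABG and complex-PCI strata are matched to the IPD separately; balance
is reported as standardized mean differences (SMDs) before and after.
Greedy matching is order-dependent, so the processing order is randomized
with a recorded seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from trialemu._seeds import derive_rng

__all__ = [
    "MatchSpec",
    "MatchResult",
    "SeparationError",
    "fit_propensity",
    "nn_match",
    "match_to_ipd",
    "standardized_mean_difference",
]


class SeparationError(RuntimeError):
    """Perfect separation in the propensity model; review the covariates."""


@dataclass
class MatchSpec:
    covariates: list = field(
        default_factory=lambda: [
            "age",
            "male",
            "diabetes",
            "hypertension",
            "lipidaemia",
            "ckd",
            "prior_mi",
            "pvd",
        ]
    )
    caliper: float = 0.01
    replacement: bool = False
    order_seed: int = 0

    def __post_init__(self) -> None:
        if self.caliper <= 0:
            raise ValueError("caliper must be > 0")
        if not self.covariates:
            raise ValueError("covariates must be non-empty")


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns: cohort_id, ipd_id, distance [, stratum]
    matched: pd.DataFrame  # matched cohort rows
    balance: pd.DataFrame  # per-covariate SMD before/after (as fractions)
    n_dropped_missing: int = 0


def standardized_mean_difference(values_a, values_b) -> float:
    """SMD between two samples, as a fraction (multiply by 100 for percent).

    Continuous: ``(mean_a - mean_b) / sqrt((var_a + var_b)/2)`` with
    unbiased variances. Binary (values all 0/1): the proportion analogue
    ``(p_a - p_b) / sqrt((p_a(1-p_a) + p_b(1-p_b))/2)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    binary = set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}
    if binary:
        pa, pb = a.mean(), b.mean()
        pooled = (pa * (1 - pa) + pb * (1 - pb)) / 2.0
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 observations per group for a continuous SMD")
        pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2.0
        pa, pb = a.mean(), b.mean()
    if pooled == 0.0:
        if pa == pb:
            return 0.0
        raise ValueError("undefined SMD: zero pooled variance with unequal means")
    return float((pa - pb) / np.sqrt(pooled))


def fit_propensity(
    combined: pd.DataFrame,
    spec: MatchSpec,
    membership_col: str = "is_ipd",
    link: str = "logit",
) -> pd.Series:
    """Membership propensity scores from a logistic (or probit) model.

    Rows with missing covariate values are dropped; scores are returned as a
    Series aligned to the surviving index of ``combined``.
    """
    cols = spec.covariates + [membership_col]
    data = combined[cols].dropna()
    X = sm.add_constant(data[spec.covariates].astype(float), has_constant="add")
    y = data[membership_col].astype(int)
    model = sm.Logit(y, X) if link == "logit" else sm.Probit(y, X)
    try:
        from trialemu.estimators import fit_discrete

        with np.errstate(all="ignore"):
            res = fit_discrete(model)
    except Exception as exc:  # statsmodels raises on hard separation
        raise SeparationError(
            "propensity model failed to fit (possible perfect separation); "
            "review the matching covariates"
        ) from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
        raise SeparationError(
            "propensity model shows perfect separation; review the matching covariates"
        )
    return pd.Series(res.predict(X), index=data.index, name="propensity")


def nn_match(
    claimant_scores: pd.Series, candidate_scores: pd.Series, spec: MatchSpec
) -> pd.DataFrame:
    """Greedy nearest-neighbour 1:1 matching within the caliper.

    Claimants are processed in a seeded random order; each claims its nearest
    candidate on the propensity scale if within ``spec.caliper``. Without
    replacement, a candidate anchors at most one claimant. Distance ties
    break to the lower candidate id. Returns a DataFrame with columns
    ``claimant_id``, ``candidate_id``, ``distance``.
    """
    if len(claimant_scores) == 0 or len(candidate_scores) == 0:
        raise ValueError("empty stratum: both claimants and candidates are required")
    cand_ids = candidate_scores.index.to_numpy()
    cand_vals = candidate_scores.to_numpy(dtype=float)
    # tie-break determinism: equal scores ordered by id
    order = np.lexsort((cand_ids, cand_vals))
    cand_ids, cand_vals = cand_ids[order], cand_vals[order]
    m = len(cand_vals)
    used = np.zeros(m, dtype=bool)

    rng = derive_rng(spec.order_seed, "nn_match")
    claim_order = rng.permutation(len(claimant_scores))
    claim_ids = claimant_scores.index.to_numpy()[claim_order]
    claim_vals = claimant_scores.to_numpy(dtype=float)[claim_order]

    pairs = []
    n_active = m
    for cid, score in zip(claim_ids, claim_vals):
        if n_active == 0 and not spec.replacement:
            break
        pos = int(np.searchsorted(cand_vals, score))
        left = pos - 1
        if not spec.replacement:
            while left >= 0 and used[left]:
                left -= 1
        right = pos
        if not spec.replacement:
            while right < m and used[right]:
                right += 1
        best_j = -1
        if left >= 0 and right < m:
            dl, dr = score - cand_vals[left], cand_vals[right] - score
            if dl < dr:
                best_j = left
            elif dr < dl:
                best_j = right
            else:  # tie: lower candidate id
                best_j = left if cand_ids[left] < cand_ids[right] else right
        elif left >= 0:
            best_j = left
        elif right < m:
            best_j = right
        if best_j >= 0:
            d = abs(score - cand_vals[best_j])
            if d <= spec.caliper:
                pairs.append((cid, cand_ids[best_j], d))
                if not spec.replacement:
                    used[best_j] = True
                    n_active -= 1
    return pd.DataFrame(pairs, columns=["claimant_id", "candidate_id", "distance"])


def match_to_ipd(
    cohort: pd.DataFrame,
    ipd: pd.DataFrame,
    spec: MatchSpec | None = None,
    strata_col: str = "arm",
) -> MatchResult:
    """Match each treatment stratum of the cohort to the trial IPD.

    Fits one propensity model per stratum on the stacked stratum+IPD table,
    matches cohort claimants to IPD candidate anchors (1:1 per stratum when
    replacement is off), and reports cohort-vs-IPD SMDs before and after.
    All unmatched cohort individuals are excluded from ``matched``.
    """
    spec = spec or MatchSpec()
    all_pairs = []
    n_dropped = 0
    for stratum, grp in cohort.groupby(strata_col, sort=True):
        stacked = pd.concat(
            [
                grp[spec.covariates].assign(is_ipd=0, _source="cohort", _orig=grp.index),
                ipd[spec.covariates].assign(is_ipd=1, _source="ipd", _orig=ipd.index),
            ],
            ignore_index=True,
        )
        n_before = len(stacked)
        scores = fit_propensity(stacked, spec)
        n_dropped += n_before - len(scores)
        meta = stacked.loc[scores.index]
        # IPD anchors claim their nearest cohort twin, so the matched cohort
        # reproduces the trial population's covariate mix
        claim = scores[meta["_source"] == "ipd"]
        cand = scores[meta["_source"] == "cohort"]
        pairs = nn_match(claim, cand, spec)
        pairs["ipd_id"] = meta.loc[pairs["claimant_id"], "_orig"].to_numpy()
        pairs["cohort_id"] = meta.loc[pairs["candidate_id"], "_orig"].to_numpy()
        pairs["stratum"] = stratum
        all_pairs.append(pairs[["stratum", "cohort_id", "ipd_id", "distance"]])
    pairs = pd.concat(all_pairs, ignore_index=True)
    matched = cohort.loc[pairs["cohort_id"]]

    balance_rows = []
    for cov in spec.covariates:
        balance_rows.append(
            {
                "covariate": cov,
                "smd_before": standardized_mean_difference(cohort[cov].dropna(), ipd[cov].dropna()),
                "smd_after": standardized_mean_difference(matched[cov].dropna(), ipd[cov].dropna()),
            }
        )
    balance = pd.DataFrame(balance_rows)
    return MatchResult(pairs, matched, balance, n_dropped)
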