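"""Group statistics: ANCOVA with EMMs, effect sizes, χ², correlations, power.

This layer reproduces the analysis conventions of covariate-adjusted group
comparison studies run in SPSS: one-way ANCOVA per outcome with a Type-III
omnibus F for the group factor, estimated marginal means (EMMs) evaluated at
the covariate grand means of the complete cases, Bonferroni-corrected
pairwise contrasts, Cohen's d backed out of EMMs and their standard errors,
Pearson χ² (no continuity correction) for guideline adherence with
adjusted-residual post-hocs, a Pearson/Spearman/Kendall correlation suite
with pairwise-complete cases, and an a-priori sample-size search on the
noncentral F distribution matching the G*Power balanced-design convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

ALPHA = 0.05
ALPHA_BORDERLINE = 0.1
VIF_FLAG_THRESHOLD = 10.0


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    raw_p: float
    adjusted_p: float
    cohens_d: float
    ci95_low: float
    ci95_high: float


@dataclass
class GroupComparison:
    outcome_name: str
    F: float
    df_between: int
    df_error: int
    p: float
    emm: dict[str, tuple[float, float]]  # group -> (mean, SE)
    group_n: dict[str, int]
    pairwise: list[PairwiseComparison]
    n_complete: int
    n_dropped: int
    significance_tier: str  # none | borderline | significant


@dataclass
class AdherenceTable:
    observed: pd.DataFrame  # groups x {adherent, non_adherent}
    chi2: float
    df: int
    p: float
    posthoc: pd.DataFrame


# ---------------------------------------------------------------------------
# covariate screening


def vif_screen(
    covariates: pd.DataFrame, threshold: float = VIF_FLAG_THRESHOLD
) -> dict[str, float]:
    """Variance inflation factor per covariate: 1/(1-R²) from regressing it
    on the others (with intercept).  Perfect collinearity reports inf."""
    cols = list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("need at least two covariates")
    X = covariates.to_numpy(dtype=float)
    n = X.shape[0]
    if n <= len(cols) + 1:
        raise ValueError("need n > number of covariates + 1")
    out: dict[str, float] = {}
    for j, name in enumerate(cols):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def flag_high_vif(vifs: Mapping[str, float], threshold: float = VIF_FLAG_THRESHOLD) -> list[str]:
    return [k for k, v in vifs.items() if v > threshold]


# ---------------------------------------------------------------------------
# ANCOVA with estimated marginal means


def ancova(
    outcome: pd.Series | np.ndarray,
    group: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    outcome_name: str = "outcome",
    alpha: float = ALPHA,
    alpha_borderline: float = ALPHA_BORDERLINE,
) -> GroupComparison:
    """One-way ANCOVA: dummy-coded groups plus covariates, listwise deletion.

    The omnibus F for the group factor is the extra-sum-of-squares test of
    the full model against the covariates-only model (equivalent to the
    Type-III group test in a main-effects model).  EMMs are model
    predictions per group at the covariate grand means with model-based SEs;
    pairwise contrasts are Bonferroni-adjusted over all group pairs, with
    Cohen's d derived from the EMMs and SEs.
    """
    y = np.asarray(outcome, dtype=float)
    g = pd.Series(np.asarray(group, dtype=object), name="group")
    if covariates is None:
        covariates = pd.DataFrame(index=range(len(y)))
    Z = covariates.reset_index(drop=True).to_numpy(dtype=float) if len(covariates.columns) else np.empty((len(y), 0))
    all_levels = sorted(pd.unique(g.dropna()))
    ok = np.isfinite(y) & g.notna().to_numpy()
    if Z.shape[1]:
        ok &= np.isfinite(Z).all(axis=1)
    n_dropped = int((~ok).sum())
    y, Z = y[ok], Z[ok]
    g = g[ok].reset_index(drop=True)
    if Z.shape[1]:
        # a constant covariate carries no information and would only distort
        # the error df; drop it so the model degenerates cleanly to ANOVA
        keep_cov = Z.std(axis=0) > 0
        Z = Z[:, keep_cov]

    levels = sorted(pd.unique(g))
    counts = g.value_counts()
    empty = [lv for lv in all_levels if counts.get(lv, 0) == 0]
    if empty:
        raise ValueError(f"group(s) with no complete cases: {empty}")
    if len(levels) < 2:
        raise ValueError("need at least two groups with complete cases")

    n = len(y)
    k = len(levels)
    p_cov = Z.shape[1]
    D = np.zeros((n, k - 1))
    for j, lv in enumerate(levels[1:]):
        D[:, j] = (g == lv).to_numpy(dtype=float)
    X_full = np.column_stack([np.ones(n), D, Z])
    X_red = np.column_stack([np.ones(n), Z])

    beta, ss_full = _ols(X_full, y)
    _, ss_red = _ols(X_red, y)
    df_between = k - 1
    df_error = n - k - p_cov
    if df_error <= 0:
        raise ValueError("not enough complete cases for the model")
    F = ((ss_red - ss_full) / df_between) / (ss_full / df_error)
    p = float(sps.f.sf(F, df_between, df_error))

    sigma2 = ss_full / df_error
    XtX_inv = np.linalg.pinv(X_full.T @ X_full)
    cov_beta = sigma2 * XtX_inv
    zbar = Z.mean(axis=0) if p_cov else np.empty(0)

    def design_row(level: str) -> np.ndarray:
        row = np.zeros(X_full.shape[1])
        row[0] = 1.0
        if level != levels[0]:
            row[1 + levels[1:].index(level)] = 1.0
        row[k:] = zbar
        return row

    emm: dict[str, tuple[float, float]] = {}
    for lv in levels:
        x = design_row(lv)
        emm[lv] = (float(x @ beta), float(np.sqrt(x @ cov_beta @ x)))

    n_pairs = k * (k - 1) // 2
    pairwise = []
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            a, b = levels[a_i], levels[b_i]
            c = design_row(a) - design_row(b)
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov_beta @ c))
            t = est / se if se > 0 else np.inf
            raw_p = float(2 * sps.t.sf(abs(t), df_error))
            adj_p = min(1.0, raw_p * n_pairs)
            d, lo, hi = cohens_d_adjusted(
                emm[a][0], emm[a][1], int(counts[a]),
                emm[b][0], emm[b][1], int(counts[b]),
            )
            pairwise.append(PairwiseComparison(a, b, raw_p, adj_p, d, lo, hi))

    tier = "significant" if p < alpha else ("borderline" if p < alpha_borderline else "none")
    return GroupComparison(
        outcome_name=outcome_name,
        F=float(F),
        df_between=df_between,
        df_error=df_error,
        p=p,
        emm=emm,
        group_n={lv: int(counts[lv]) for lv in levels},
        pairwise=pairwise,
        n_complete=n,
        n_dropped=n_dropped,
        significance_tier=tier,
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def cohens_d_adjusted(
    emm_a: float, se_a: float, n_a: int,
    emm_b: float, se_b: float, n_b: int,
) -> tuple[float, float, float]:
    """Cohen's d from EMMs and their SEs: per-group SD is SE·√n, pooled with
    (n-1) weights; the 95% CI uses the large-sample SE of d,
    √((n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b-2))).  Returns (d, lo, hi); NaNs
    when the pooled SD is zero."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    s_a = se_a * np.sqrt(n_a)
    s_b = se_b * np.sqrt(n_b)
    s_pooled = np.sqrt(((n_a - 1) * s_a**2 + (n_b - 1) * s_b**2) / (n_a + n_b - 2))
    if s_pooled == 0:
        return float("nan"), float("nan"), float("nan")
    d = (emm_a - emm_b) / s_pooled
    se_d = np.sqrt((n_a + n_b) / (n_a * n_b) + d**2 / (2 * (n_a + n_b - 2)))
    z = sps.norm.ppf(0.975)
    return float(d), float(d - z * se_d), float(d + z * se_d)


def cohens_d_raw(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Cohen's d straight from two raw samples (oracle route)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return cohens_d_adjusted(
        a.mean(), a.std(ddof=1) / np.sqrt(len(a)), len(a),
        b.mean(), b.std(ddof=1) / np.sqrt(len(b)), len(b),
    )


# ---------------------------------------------------------------------------
# chi-square on adherence


def chi_square_independence(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson χ² of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def adherence_posthoc(table: pd.DataFrame, pairwise_tables: bool = False) -> pd.DataFrame:
    """Per-group post-hoc after a groups × {adherent, non-adherent} χ².

    Default: adjusted standardized residuals per group with two-sided normal
    p-values, Bonferroni-corrected over the number of groups.  With
    ``pairwise_tables=True``: each group against the rest pooled as a 2×2
    Pearson χ², same correction.
    """
    obs = table.to_numpy(dtype=float)
    groups = list(table.index)
    n = obs.sum()
    rows = []
    for i, gname in enumerate(groups):
        if pairwise_tables:
            rest = obs.sum(axis=0) - obs[i]
            chi2, df, p = chi_square_independence(np.vstack([obs[i], rest]))
            stat = chi2
        else:
            row_tot = obs[i].sum()
            col_tot = obs[:, 0].sum()
            e = row_tot * col_tot / n
            denom = np.sqrt(e * (1 - row_tot / n) * (1 - col_tot / n))
            stat = (obs[i, 0] - e) / denom if denom > 0 else np.nan
            p = float(2 * sps.norm.sf(abs(stat)))
        rows.append(
            {
                "group": gname,
                "statistic": float(stat),
                "raw_p": float(p),
                "adjusted_p": float(min(1.0, p * len(groups))),
            }
        )
    return pd.DataFrame(rows)


def adherence_test(
    adherent: Mapping[str, int], group_sizes: Mapping[str, int],
    pairwise_tables: bool = False,
) -> AdherenceTable:
    groups = list(group_sizes)
    obs = pd.DataFrame(
        {
            "adherent": [adherent[g] for g in groups],
            "non_adherent": [group_sizes[g] - adherent[g] for g in groups],
        },
        index=groups,
    )
    chi2, df, p = chi_square_independence(obs)
    return AdherenceTable(obs, chi2, df, p, adherence_posthoc(obs, pairwise_tables))


# ---------------------------------------------------------------------------
# correlations and regressions


PAB_VARS = ("sitting", "standing", "stepping")
COG_VARS = ("inhibition", "shifting", "updating")


def association_suite(
    pab: pd.DataFrame,
    scores: pd.DataFrame,
    pab_vars: Sequence[str] = PAB_VARS,
    cog_vars: Sequence[str] = COG_VARS,
    alpha: float = ALPHA,
) -> dict:
    """Zero-order correlations and per-outcome regressions, pairwise complete.

    For each (activity, cognition) pair: Pearson r, Spearman rho, and
    Kendall tau-b with p-values and the pairwise-complete n.  For each
    cognitive outcome: an OLS regression on the three activity variables
    (listwise within that regression).  Both tables are keyed by the merged
    participant table, so differing per-cell ns are reported, not hidden.
    """
    merged = pab.merge(scores, on="participant_id", how="inner")
    corr_rows = []
    for pv in pab_vars:
        for cv in cog_vars:
            sub = merged[[pv, cv]].dropna()
            n = len(sub)
            row = {"pab_var": pv, "cog_var": cv, "n": n}
            if n < 3 or sub[pv].nunique() < 2 or sub[cv].nunique() < 2:
                for m in ("pearson", "spearman", "kendall"):
                    row[f"{m}_r"] = row[f"{m}_p"] = float("nan")
            else:
                x, y = sub[pv].to_numpy(float), sub[cv].to_numpy(float)
                r, p = sps.pearsonr(x, y)
                row["pearson_r"], row["pearson_p"] = float(r), float(p)
                r, p = sps.spearmanr(x, y)
                row["spearman_r"], row["spearman_p"] = float(r), float(p)
                r, p = sps.kendalltau(x, y)  # tau-b: handles ties
                row["kendall_r"], row["kendall_p"] = float(r), float(p)
            row["significant"] = bool(row["pearson_p"] < alpha) if np.isfinite(row["pearson_p"]) else False
            corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)

    regressions = {}
    for cv in cog_vars:
        sub = merged[list(pab_vars) + [cv]].dropna()
        if len(sub) < len(pab_vars) + 2:
            regressions[cv] = {"n": len(sub), "coefficients": None}
            continue
        X = np.column_stack([np.ones(len(sub))] + [sub[pv].to_numpy(float) for pv in pab_vars])
        y = sub[cv].to_numpy(float)
        beta, ss_res = _ols(X, y)
        df_error = len(sub) - X.shape[1]
        sigma2 = ss_res / df_error
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2 * sps.t.sf(np.abs(tvals), df_error)
        regressions[cv] = {
            "n": int(len(sub)),
            "coefficients": {
                name: {"beta": float(b), "se": float(s), "t": float(t), "p": float(p)}
                for name, b, s, t, p in zip(
                    ["intercept", *pab_vars], beta, se, tvals, pvals
                )
            },
        }
    return {"correlations": correlations, "regressions": regressions}


def subset_sensitivity(
    pab: pd.DataFrame,
    scores: pd.DataFrame,
    exclusion_flags: pd.DataFrame,
    min_n: int = 10,
    alpha: float = ALPHA,
) -> dict:
    """Re-run the association suite excluding each flagged subgroup.

    ``exclusion_flags``: participant_id plus one boolean column per flag;
    flagged participants are removed for that flag's subset analysis.
    Subsets smaller than ``min_n`` are skipped with a warning.  Reports, per
    subset, whether each cell's Pearson sign and significance agree with the
    full-sample result.
    """
    full = association_suite(pab, scores, alpha=alpha)
    full_corr = full["correlations"]
    out = {"full": full, "subsets": {}}
    flag_cols = [c for c in exclusion_flags.columns if c != "participant_id"]
    for flag in flag_cols:
        keep_ids = exclusion_flags.loc[~exclusion_flags[flag].astype(bool), "participant_id"]
        sub_pab = pab[pab["participant_id"].isin(keep_ids)]
        if len(sub_pab) < min_n:
            warnings.warn(f"subset {flag!r} has n={len(sub_pab)} < {min_n}; skipped")
            out["subsets"][flag] = {"skipped": True, "n": int(len(sub_pab))}
            continue
        res = association_suite(sub_pab, scores, alpha=alpha)
        cmp = res["correlations"].merge(
            full_corr, on=["pab_var", "cog_var"], suffixes=("", "_full")
        )
        cmp["sign_agrees"] = np.sign(cmp["pearson_r"]) == np.sign(cmp["pearson_r_full"])
        cmp["significance_agrees"] = cmp["significant"] == cmp["significant_full"]
        out["subsets"][flag] = {
            "skipped": False,
            "n": int(len(sub_pab)),
            "result": res,
            "agreement": cmp[
                ["pab_var", "cog_var", "sign_agrees", "significance_agrees"]
            ],
            "conclusions_unchanged": bool(cmp["significance_agrees"].all()),
        }
    return out


# ---------------------------------------------------------------------------
# a-priori power


def anova_power(n_total: int, k_groups: int, f: float, alpha: float = ALPHA) -> float:
    """Power of the one-way ANOVA omnibus F test at total N, Cohen's f."""
    df1 = k_groups - 1
    df2 = n_total - k_groups
    if df2 < 1:
        return 0.0
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, f * f * n_total))


def anova_power_n(
    k_groups: int,
    f: float,
    alpha: float = ALPHA,
    power: float = 0.8,
    equal_groups: bool = True,
    n_max: int = 1_000_000,
) -> int:
    """Smallest total N reaching the target power (noncentral F, λ = f²·N).

    ``equal_groups=True`` (the G*Power a-priori convention) searches over
    balanced designs, so the answer is a multiple of ``k_groups``;
    ``equal_groups=False`` searches every integer total.
    """
    if k_groups < 2:
        raise ValueError("need at least two groups")
    if not 0 < alpha < power < 1:
        raise ValueError("need 0 < alpha < power < 1")
    if f <= 0:
        raise ValueError("effect size f must be > 0")
    step = k_groups if equal_groups else 1
    start = k_groups + 1
    if equal_groups:
        start = k_groups * max(2, int(np.ceil((k_groups + 1) / k_groups)))
    n = start
    while n <= n_max:
        if anova_power(n, k_groups, f, alpha) >= power:
            return int(n)
        n += step
    raise ValueError("no feasible N below n_max")
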