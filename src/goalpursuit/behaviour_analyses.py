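"""Cohort-level behavioural statistics for the goal-pursuit task.

Covers the study's behavioural claims: a goal-progress effect on abandonment
beyond tree-search value, the temptation/frustration asymmetry (alternative
value loses influence across goal progress faster than current-goal value),
spatial-attention metrics and their link to persistence biases, the
goal-completion performance metric, and permutation tests for group
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats



class ProgressBiasTest(NamedTuple):
    """Likelihood-ratio test for a goal-progress effect beyond model value."""

    chi2: float
    df: int
    p: float
    beta_progress: float


def progress_bias_test(dataset: pd.DataFrame, sv_col: str = "sv_tree_search") -> ProgressBiasTest:
    """Does goal progress predict abandonment on top of tree-search value?

    Pooled logistic regressions of abandonment on {sv} versus {sv, progress};
    the deviance difference is referred to chi-square(1).  A negative progress
    coefficient means people grow *more* reluctant to abandon as the net
    fills, over and above the planner's valuation.
    """
    y = dataset["abandon"].to_numpy(dtype=float)
    sv = dataset[sv_col].to_numpy(dtype=float)
    progress = dataset["progress"].to_numpy(dtype=float)
    X0 = sm.add_constant(sv)
    X1 = np.column_stack([X0, progress])
    try:
        fit0 = sm.Logit(y, X0).fit(disp=0)
        fit1 = sm.Logit(y, X1).fit(disp=0)
    except Exception as exc:  # non-convergence / separation
        raise RuntimeError(f"progress bias test failed to converge: {exc}") from exc
    chi2 = max(0.0, 2.0 * (fit1.llf - fit0.llf))
    return ProgressBiasTest(
        chi2=float(chi2),
        df=1,
        p=float(stats.chi2.sf(chi2, 1)),
        beta_progress=float(fit1.params[-1]),
    )


@dataclass
class InteractionFit:
    """Per-participant value x progress interaction regression.

    Both value sources are coded as *pressure to abandon*: the alternative
    value enters as-is and the current-goal value sign-flipped (frustration),
    so both main effects are positive and a negative interaction with
    progress means that source of pressure loses influence as the net fills.
    ``coefs`` columns: b_alt, b_frust, b_alt_x_progress, b_frust_x_progress.
    """

    coefs: pd.DataFrame
    t_alt_x_progress: float
    p_alt_x_progress: float
    t_frust_x_progress: float
    p_frust_x_progress: float
    paired_t: float
    paired_p: float  # two-sided
    n_excluded: int

    @property
    def mean_slope_difference(self) -> float:
        """Mean of (alt x progress) - (frustration x progress) coefficients."""
        return float((self.coefs["b_alt_x_progress"] - self.coefs["b_frust_x_progress"]).mean())

    def asymmetry_detected(self, alpha: float = 0.05) -> bool:
        """One-sided: alternative-value influence fades faster than goal-value."""
        return self.mean_slope_difference < 0 and self.paired_p / 2.0 < alpha

    def summary(self) -> str:
        return "\n".join(
            [
                "Value x progress interaction (pressure coding)",
                f"  participants: {len(self.coefs)} ({self.n_excluded} excluded)",
                f"  alt x progress:         t = {self.t_alt_x_progress:.2f}, p = {self.p_alt_x_progress:.3g}",
                f"  frustration x progress: t = {self.t_frust_x_progress:.2f}, p = {self.p_frust_x_progress:.3g}",
                f"  paired difference:      t = {self.paired_t:.2f}, p = {self.paired_p:.3g}"
                f" (mean diff {self.mean_slope_difference:.3f})",
            ]
        )


def value_progress_interaction(
    dataset: pd.DataFrame,
    standardize: bool = True,
    ridge: float = 1e-4,
) -> InteractionFit:
    """Fit per-participant logistics of abandonment on value x progress terms.

    Predictors per participant: best-alternative tree-search value,
    sign-flipped current-goal value, goal progress, and each value
    interacted with progress.  The progress main effect must be present
    because attenuating a value with a nonzero mean induces one; omitting it
    biases the interaction estimates.  With ``standardize`` the two value
    predictors are centred and divided by a *common* scale (the mean of
    their standard deviations) so the two interaction coefficients stay
    directly comparable and their paired difference is zero when both value
    sources attenuate at the same rate.  Cohort-level two-sided t-tests
    compare the interaction coefficients against zero and against each
    other.
    """
    from .fitting import _ridge_irls

    records = []
    n_excluded = 0
    for pid, grp in dataset.groupby("pid", sort=False):
        v_alt = grp["v_altbest_ts"].to_numpy(dtype=float)
        v_frust = -grp["v_goal_ts"].to_numpy(dtype=float)
        progress = grp["progress"].to_numpy(dtype=float)
        y = grp["abandon"].to_numpy(dtype=float)
        if standardize:
            scale = 0.5 * (v_alt.std() + v_frust.std())
            if scale > 0:
                v_alt = (v_alt - v_alt.mean()) / scale
                v_frust = (v_frust - v_frust.mean()) / scale
        X = np.column_stack(
            [
                np.ones_like(y),
                v_alt,
                v_frust,
                progress,
                v_alt * progress,
                v_frust * progress,
            ]
        )
        if y.min() == y.max():
            n_excluded += 1
            warnings.warn(f"participant {pid}: constant choices, excluded from interaction fit")
            continue
        beta, _, converged, _ = _ridge_irls(X, y, ridge=ridge)
        if not converged or np.max(np.abs(beta)) > 50.0:
            n_excluded += 1
            warnings.warn(f"participant {pid}: interaction fit flagged, excluded")
            continue
        records.append(
            {
                "pid": pid,
                "b_alt": beta[1],
                "b_frust": beta[2],
                "b_progress": beta[3],
                "b_alt_x_progress": beta[4],
                "b_frust_x_progress": beta[5],
            }
        )
    coefs = pd.DataFrame(records).set_index("pid")
    if len(coefs) < 2:
        raise ValueError("too few participants with usable interaction fits")
    t_alt, p_alt = stats.ttest_1samp(coefs["b_alt_x_progress"], 0.0)
    t_fr, p_fr = stats.ttest_1samp(coefs["b_frust_x_progress"], 0.0)
    t_pair, p_pair = stats.ttest_rel(coefs["b_alt_x_progress"], coefs["b_frust_x_progress"])
    return InteractionFit(
        coefs=coefs,
        t_alt_x_progress=float(t_alt),
        p_alt_x_progress=float(p_alt),
        t_frust_x_progress=float(t_fr),
        p_frust_x_progress=float(p_fr),
        paired_t=float(t_pair),
        paired_p=float(p_pair),
        n_excluded=n_excluded,
    )


@dataclass
class AttentionMetrics:
    """Spatial-attention summary per participant plus cohort tests.

    ``per_participant`` columns: mean_err_goal, mean_err_alt, atten_bias
    (alt minus goal error; positive = goal advantage), slope_goal, slope_alt
    (error change per trial invested), mean_rt_goal, mean_rt_alt.
    """

    per_participant: pd.DataFrame
    err_t: float
    err_p: float
    rt_t: float
    rt_p: float
    slope_t: float
    slope_p: float
    n_flagged: int

    def summary(self) -> str:
        pp = self.per_participant
        return "\n".join(
            [
                "Spatial attention metrics",
                f"  participants: {len(pp)} ({self.n_flagged} flagged)",
                f"  mean error  goal {pp['mean_err_goal'].mean():.4f} vs alt {pp['mean_err_alt'].mean():.4f}"
                f"  (paired t = {self.err_t:.2f}, p = {self.err_p:.3g})",
                f"  mean RT     goal {pp['mean_rt_goal'].mean():.3f} vs alt {pp['mean_rt_alt'].mean():.3f}"
                f"  (paired t = {self.rt_t:.2f}, p = {self.rt_p:.3g})",
                f"  error slope goal {pp['slope_goal'].mean():.5f} vs alt {pp['slope_alt'].mean():.5f}"
                f"  (paired t = {self.slope_t:.2f}, p = {self.slope_p:.3g})",
            ]
        )


def attention_analysis(spatial_log: pd.DataFrame) -> AttentionMetrics:
    """Per-participant error/RT means and trials-invested slopes by status.

    First trials of blocks (no goal yet) are excluded.  The slope is the OLS
    coefficient of report error on trials invested, fitted separately for the
    current-goal stimulus and for alternatives; cohort-level paired t-tests
    compare goal versus alternative error, RT, and slopes.
    """
    log = spatial_log[~spatial_log["first_trial"].astype(bool)]
    records = []
    n_flagged = 0
    for pid, grp in log.groupby("pid", sort=False):
        rec = {"pid": pid}
        usable = True
        for status, suffix in (("goal", "goal"), ("alt", "alt")):
            sub = grp[grp["stimulus_status"] == status]
            if len(sub) < 2 or sub["trials_invested"].nunique() < 2:
                usable = False
                break
            rec[f"mean_err_{suffix}"] = sub["error"].mean()
            rec[f"mean_rt_{suffix}"] = sub["rt"].mean()
            slope, _, _, _, _ = stats.linregress(sub["trials_invested"], sub["error"])
            rec[f"slope_{suffix}"] = slope
        if not usable:
            n_flagged += 1
            warnings.warn(f"participant {pid}: too few spatial trials, flagged")
            continue
        rec["atten_bias"] = rec["mean_err_alt"] - rec["mean_err_goal"]
        records.append(rec)
    pp = pd.DataFrame(records).set_index("pid")
    if len(pp) < 2:
        raise ValueError("too few participants with usable spatial data")
    err_t, err_p = stats.ttest_rel(pp["mean_err_goal"], pp["mean_err_alt"])
    rt_t, rt_p = stats.ttest_rel(pp["mean_rt_goal"], pp["mean_rt_alt"])
    slope_t, slope_p = stats.ttest_rel(pp["slope_goal"], pp["slope_alt"])
    return AttentionMetrics(
        per_participant=pp,
        err_t=float(err_t),
        err_p=float(err_p),
        rt_t=float(rt_t),
        rt_p=float(rt_p),
        slope_t=float(slope_t),
        slope_p=float(slope_p),
        n_flagged=n_flagged,
    )


class BiasCorrelation(NamedTuple):
    rho: float
    p: float
    ci_low: float
    ci_high: float
    n: int


def bias_correlation(atten_bias, ip, ci_level: float = 0.95) -> BiasCorrelation:
    """Spearman correlation between attention bias and persistence bias.

    The confidence interval uses the Fisher transform of the rank correlation
    with s.e. 1/sqrt(n - 3) — a documented approximation for Spearman's rho.
    """
    a = np.asarray(atten_bias, dtype=float)
    b = np.asarray(ip, dtype=float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need >= 5 paired observations")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(a, b)
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = zcrit / np.sqrt(a.size - 3)
    return BiasCorrelation(
        rho=float(rho),
        p=float(p),
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
        n=int(a.size),
    )


def performance_metric(choice_log: pd.DataFrame) -> float:
    """Mean number of trials taken to complete a net (lower = better).

    Blocks the session ended before completing are excluded.
    """
    completed = []
    for _, grp in choice_log.groupby(["participant", "block"], sort=False):
        if grp["completed_net"].any():
            completed.append(len(grp))
    if not completed:
        raise ValueError("no completed nets in this log")
    return float(np.mean(completed))


def ip_sign_test(ips, alternative: str = "greater") -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of indifference points against 0.

    Exact null distribution for n <= 25, normal approximation otherwise.
    Returns (statistic, p).
    """
    ips = np.asarray(ips, dtype=float)
    method = "exact" if ips.size <= 25 and not np.any(ips == 0) else "approx"
    res = stats.wilcoxon(ips, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def perm_test_means(
    group_a,
    group_b,
    n_perm: int = 10_000,
    side: str = "greater",
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Permutation test for a difference in means (a minus b).

    ``side``: 'greater', 'less' or 'two-sided'.  P-values use the add-one
    convention (b + 1) / (n_perm + 1).  Returns (observed_diff, p).
    """
    if rng is None:
        rng = np.random.default_rng()
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values will be coarse")
    pooled = np.concatenate([a, b])
    observed = a.mean() - b.mean()
    count = 0
    n_a = a.size
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[:n_a].mean() - perm[n_a:].mean()
        if side == "greater":
            count += diff >= observed
        elif side == "less":
            count += diff <= observed
        elif side == "two-sided":
            count += abs(diff) >= abs(observed)
        else:
            raise ValueError(f"unknown side: {side!r}")
    return float(observed), float((count + 1) / (n_perm + 1))
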