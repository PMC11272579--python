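"""Fitting choice models to abandonment behaviour.

The central object is :class:`PersistenceLogit`, a two-parameter logistic
model of abandonment choices,

    P(abandon) = 1 / (1 + exp(-(beta0 + beta1 * sv))),

where ``sv`` is a valuation model's subjective value of abandonment (best
alternative value minus current-goal value).  ``fit()`` returns a
:class:`PersistenceLogitResults` carrying the estimates, their standard
errors, and the participant's *indifference point* IP = -beta0 / beta1 — the
abandonment value at which switching becomes as likely as persisting.  A
positive IP quantifies a persistence bias: the alternatives must look better
than the model's prediction before the person is willing to abandon.
beta1 is the inverse temperature (choice consistency).

The module also builds trial-level datasets from choice logs, compares the
four valuation models by leave-one-out cross-validation across participants,
and runs parameter-recovery simulations.  The published analysis used a
mixed-effects logistic for the group fit; here individual indifference points
come from per-participant maximum likelihood and the cross-validation step
uses a pooled fixed-effects fit — a deliberate, documented simplification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import agents
from .task_engine import Schedule, TaskState

ALL_MODELS = agents.MODEL_NAMES

#: |beta| above which a fit is flagged as (quasi-)separated.
_BETA_BOUND = 50.0


class DataIntegrityError(ValueError):
    """Choice log and schedule disagree (offers or block structure)."""


class RecoverySkipped(RuntimeError):
    """Parameter recovery is not meaningful for the supplied data."""


def _ridge_irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-4,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Newton/IRLS for ridge-penalised logistic regression.

    Returns ``(beta, cov, converged, n_iter)`` where ``cov`` is the inverse of
    the penalised observed information.  Deterministic given the data.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = agents.sigmoid(eta)
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(p)
        g = X.T @ (y - mu) - ridge * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e6:
            converged = False
            break
    eta = X @ beta
    mu = agents.sigmoid(eta)
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None]) + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged, it


class PersistenceLogit:
    """Logistic model of abandonment on a single subjective-value predictor.

    Parameters
    ----------
    abandon : array-like of 0/1
        Abandonment indicator per (non-first) trial.
    sv : array-like
        Model value of abandonment per trial.
    model_name : str
        Which valuation model produced ``sv`` (bookkeeping only).
    ridge : float
        Small L2 penalty stabilising near-separated fits.
    """

    def __init__(self, abandon, sv, model_name: str = "tree_search", ridge: float = 1e-4):
        y = np.asarray(abandon, dtype=float)
        x = np.asarray(sv, dtype=float)
        ok = np.isfinite(y) & np.isfinite(x)
        self.endog = y[ok]
        self.sv = x[ok]
        if self.endog.size == 0:
            raise ValueError("no finite observations")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("abandon must be binary")
        self.model_name = model_name
        self.ridge = float(ridge)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        model: str = "tree_search",
        abandon_col: str = "abandon",
        ridge: float = 1e-4,
    ) -> "PersistenceLogit":
        """Build from a trial-level dataset with ``sv_<model>`` columns."""
        sv_col = f"sv_{model}"
        if sv_col not in data.columns:
            raise KeyError(f"column {sv_col!r} not in dataset")
        return cls(data[abandon_col], data[sv_col], model_name=model, ridge=ridge)

    @property
    def exog(self) -> np.ndarray:
        return np.column_stack([np.ones_like(self.sv), self.sv])

    def loglike(self, params: Sequence[float], penalised: bool = True) -> float:
        """Bernoulli log-likelihood (optionally ridge-penalised)."""
        params = np.asarray(params, dtype=float)
        eta = self.exog @ params
        # log(1 + e^eta) computed stably
        ll = float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))
        if penalised:
            ll -= 0.5 * self.ridge * float(params @ params)
        return ll

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "PersistenceLogitResults":
        flag = None
        if self.endog.min() == self.endog.max():
            flag = "separation"  # all-persist or all-abandon
        elif np.std(self.sv) == 0.0:
            flag = "degenerate_predictor"
        if flag is not None:
            return PersistenceLogitResults(
                model=self,
                params=np.array([np.nan, np.nan]),
                cov=np.full((2, 2), np.nan),
                converged=False,
                flag=flag,
                n_iter=0,
            )
        beta, cov, converged, n_iter = _ridge_irls(
            self.exog, self.endog, ridge=self.ridge, tol=tol, max_iter=max_iter
        )
        if converged and np.max(np.abs(beta)) > _BETA_BOUND:
            converged = False
            flag = "separation"
        elif not converged:
            flag = "non_convergence"
        return PersistenceLogitResults(
            model=self,
            params=beta,
            cov=cov,
            converged=converged,
            flag=flag,
            n_iter=n_iter,
        )


@dataclass
class PersistenceLogitResults:
    """Results of a :class:`PersistenceLogit` fit."""

    model: PersistenceLogit
    params: np.ndarray  # (beta0, beta1)
    cov: np.ndarray
    converged: bool
    flag: Optional[str]
    n_iter: int

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta1(self) -> float:
        """Inverse temperature: slope on the model value of abandonment."""
        return float(self.params[1])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def n_obs(self) -> int:
        return int(self.model.endog.size)

    @property
    def llf(self) -> float:
        return self.model.loglike(self.params, penalised=False)

    def indifference_point(self, tol: float = 1e-6) -> float:
        """IP = -beta0/beta1, the abandonment value where P(abandon) = 0.5."""
        if not self.converged:
            raise ValueError(f"fit not usable (flag={self.flag})")
        if abs(self.beta1) <= tol:
            raise ValueError("indifference point undefined: |beta1| below tolerance")
        return -self.beta0 / self.beta1

    def predict(self, sv) -> np.ndarray:
        """Predicted abandonment probability at the given values."""
        sv = np.asarray(sv, dtype=float)
        return agents.sigmoid(self.beta0 + self.beta1 * sv)

    def summary(self) -> str:
        lines = [
            f"PersistenceLogit results ({self.model.model_name})",
            f"  n_obs      : {self.n_obs}",
            f"  converged  : {self.converged}" + (f" [{self.flag}]" if self.flag else ""),
        ]
        if self.converged:
            se = self.bse
            lines += [
                f"  beta0      : {self.beta0: .4f} (se {se[0]:.4f})",
                f"  beta1      : {self.beta1: .4f} (se {se[1]:.4f})",
                f"  IP         : {self.indifference_point(): .4f}",
                f"  loglik     : {self.llf: .2f}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None, n_bins: int = 8):
        """Plot the fitted abandonment curve over binned observed rates."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sv = self.model.sv
        y = self.model.endog
        grid = np.linspace(sv.min(), sv.max(), 200)
        ax.plot(grid, self.predict(grid), color="C0", label="fit")
        edges = np.quantile(sv, np.linspace(0, 1, n_bins + 1))
        centers, rates = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (sv >= lo) & (sv <= hi)
            if sel.any():
                centers.append(sv[sel].mean())
                rates.append(y[sel].mean())
        ax.plot(centers, rates, "o", color="C1", label="observed")
        if self.converged and abs(self.beta1) > 1e-6:
            ax.axvline(self.indifference_point(), color="green", ls="--", label="IP")
        ax.set_xlabel("abandonment value (sv)")
        ax.set_ylabel("P(abandon)")
        ax.legend()
        return ax


def fit_logistic(
    data: pd.DataFrame,
    model: str = "tree_search",
    ridge: float = 1e-4,
) -> PersistenceLogitResults:
    """Convenience wrapper: fit one participant's rows for one model."""
    return PersistenceLogit.from_dataframe(data, model=model, ridge=ridge).fit()


def indifference_point(fit: PersistenceLogitResults, tol: float = 1e-6) -> float:
    """IP = -beta0/beta1 (persistence bias when positive)."""
    return fit.indifference_point(tol=tol)


def _replay_states(choice_log: pd.DataFrame, schedule: Schedule) -> Iterable[tuple]:
    """Yield (row, TaskState) for every trial, validating against the schedule."""
    blocks = {b.block_id: b for b in schedule.blocks}
    for (pid, block_id), grp in choice_log.groupby(["participant", "block"], sort=False):
        block = blocks.get(block_id)
        if block is None:
            raise DataIntegrityError(f"block {block_id} not in schedule")
        grp = grp.sort_values("trial")
        for _, row in grp.iterrows():
            t = int(row["trial"])
            offers = np.array([row["offer_A"], row["offer_B"], row["offer_C"]])
            if t > block.n_trials or not np.allclose(offers, block.offers[t - 1], atol=1e-8):
                raise DataIntegrityError(
                    f"offers mismatch at participant={pid}, block={block_id}, trial={t}"
                )
            good = row["current_good"]
            state = TaskState(
                block_id=block_id,
                trial_index=t,
                net_size=float(row["net_size"]),
                accumulated=float(row["accumulated"]),
                current_good=None if pd.isna(good) else good,
                offers=offers,
                trials_invested=int(row["trials_invested"]),
            )
            yield row, state


def build_dataset(
    choice_log: pd.DataFrame,
    schedule: Schedule,
    ts_cfg: Optional[agents.TreeSearchConfig] = None,
    rng: Optional[np.random.Generator] = None,
    models: Sequence[str] = ALL_MODELS,
) -> pd.DataFrame:
    """Recompute model values at every non-first trial of a choice log.

    Returns one row per non-first trial with the abandonment indicator,
    each requested model's abandonment value ``sv_<model>``, goal progress,
    the tree-search goal/alternative values, and trials invested.  First
    trials of blocks carry no persist/abandon distinction and are excluded.
    """
    if "tree_search" in models and (ts_cfg is None or rng is None):
        raise ValueError("tree_search values require ts_cfg and rng")
    rows = []
    for row, state in _replay_states(choice_log, schedule):
        if state.current_good is None:
            continue
        rec = {
            "pid": row["participant"],
            "block": row["block"],
            "trial": row["trial"],
            "abandon": float(row["abandon"]),
            "progress": state.progress,
            "trials_invested": state.trials_invested,
        }
        for model in models:
            valuation = agents.compute_values(state, model, ts_cfg, rng)
            rec[f"sv_{model}"] = valuation.sv_abandon
            if model == "tree_search":
                rec["v_goal_ts"] = valuation.values[valuation.goal_index]
                rec["v_altbest_ts"] = valuation.values[valuation.best_alternative_index]
        rows.append(rec)
    return pd.DataFrame(rows)


def dataset_from_logged_values(choice_log: pd.DataFrame) -> pd.DataFrame:
    """Build a single-model dataset from the values recorded in a choice log.

    Uses the ``V_goal``/``V_altbest`` columns the simulator wrote (under the
    log's own model), avoiding a recomputation.  The model's sv column is
    named after the log's ``model`` field.
    """
    log = choice_log[choice_log["current_good"].notna()].copy()
    model = str(log["model"].iloc[0])
    out = pd.DataFrame(
        {
            "pid": log["participant"].values,
            "block": log["block"].values,
            "trial": log["trial"].values,
            "abandon": log["abandon"].astype(float).values,
            "progress": log["progress"].values,
            "trials_invested": log["trials_invested"].values,
            f"sv_{model}": (log["V_altbest"] - log["V_goal"]).values,
        }
    )
    if model == "tree_search":
        out["v_goal_ts"] = log["V_goal"].values
        out["v_altbest_ts"] = log["V_altbest"].values
    return out


@dataclass
class CVResult:
    """Leave-one-out cross-validation model comparison."""

    accuracy: pd.DataFrame  # index pid, columns model
    mean_accuracy: pd.Series
    best_model: pd.Series  # per pid

    def summary(self) -> str:
        lines = ["LOO-CV model comparison", "  mean accuracy per model:"]
        for model, acc in self.mean_accuracy.sort_values(ascending=False).items():
            lines.append(f"    {model:<12s} {acc:.4f}")
        counts = self.best_model.value_counts()
        lines.append("  best model frequency: " + ", ".join(f"{m}={c}" for m, c in counts.items()))
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        means = self.mean_accuracy
        sems = self.accuracy.sem()
        ax.bar(means.index, means.values, yerr=sems[means.index].values, color="C0")
        ax.set_ylabel("CV accuracy")
        ax.set_ylim(0.5, 1.0)
        return ax


def loo_cv_compare(
    dataset: pd.DataFrame,
    models: Sequence[str] = ALL_MODELS,
    ridge: float = 1e-4,
) -> CVResult:
    """Compare models by leave-one-participant-out cross-validation.

    For each held-out participant and model, a pooled logistic is fitted to
    all other participants' choices and used to predict the held-out
    participant's trialwise abandonment probabilities; accuracy is
    1 - mean |predicted probability - observed choice|.
    """
    pids = dataset["pid"].unique()
    if len(pids) < 2:
        raise ValueError("leave-one-out comparison needs >= 2 participants")
    acc = pd.DataFrame(index=pids, columns=list(models), dtype=float)
    for pid in pids:
        train = dataset[dataset["pid"] != pid]
        test = dataset[dataset["pid"] == pid]
        for model in models:
            fit = PersistenceLogit.from_dataframe(train, model=model, ridge=ridge).fit()
            if not fit.converged:
                warnings.warn(f"pooled fit failed for model={model}, held-out pid={pid}")
                continue
            p_hat = fit.predict(test[f"sv_{model}"].to_numpy())
            acc.loc[pid, model] = 1.0 - np.mean(np.abs(p_hat - test["abandon"].to_numpy()))
    return CVResult(
        accuracy=acc,
        mean_accuracy=acc.mean(axis=0),
        best_model=acc.dropna(how="all").idxmax(axis=1),
    )


@dataclass
class RecoveryReport:
    """Parameter-recovery simulation results."""

    true_ip: np.ndarray
    fitted_ip: np.ndarray
    true_inv_temp: np.ndarray
    fitted_inv_temp: np.ndarray
    ip_pearson: float
    ip_spearman: float
    inv_temp_pearson: float
    inv_temp_spearman: float
    icc: float
    n_excluded: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Parameter recovery",
                f"  participants used : {self.true_ip.size} ({self.n_excluded} excluded)",
                f"  IP        r = {self.ip_pearson:.3f} (Spearman {self.ip_spearman:.3f})",
                f"  inv. temp r = {self.inv_temp_pearson:.3f} (Spearman {self.inv_temp_spearman:.3f})",
                f"  split-half ICC of IP = {self.icc:.3f}",
            ]
        )


def _split_half_ips(
    dataset: pd.DataFrame, ridge: float = 1e-4
) -> tuple[Optional[float], Optional[float]]:
    """IPs fitted separately on even/odd blocks (pseudo test-retest halves)."""
    ips = []
    for parity in (0, 1):
        half = dataset[dataset["block"].astype(int) % 2 == parity]
        try:
            fit = PersistenceLogit.from_dataframe(half, model="tree_search", ridge=ridge).fit()
            ips.append(fit.indifference_point() if fit.converged else None)
        except (ValueError, KeyError):
            ips.append(None)
    return tuple(ips)


def recover_parameters(
    hyperparams,
    schedule: Schedule,
    rng: np.random.Generator,
    ts_cfg: Optional[agents.TreeSearchConfig] = None,
    n_session_trials: int = 300,
    refit_rollouts: Optional[int] = None,
) -> RecoveryReport:
    """Simulate a cohort with known parameters, refit, and report recovery.

    Each synthetic participant's choices are generated by the softmax
    tree-search rule with a known persistence bias and inverse temperature;
    tree-search values are then *recomputed* (independent rollouts) and the
    logistic refitted per participant, mirroring the treatment of a real
    participant.  Also reports a split-half (even/odd blocks) ICC of the
    fitted indifference points as a test-retest analogue.
    """
    from . import synthetic_cohort

    if ts_cfg is None:
        ts_cfg = agents.TreeSearchConfig(params=schedule.params)
    refit_cfg = ts_cfg
    if refit_rollouts is not None:
        refit_cfg = agents.TreeSearchConfig(
            n_rollouts=refit_rollouts, max_horizon=ts_cfg.max_horizon, params=ts_cfg.params
        )
    profiles = synthetic_cohort.gen_cohort(hyperparams, rng)
    true_ip, fitted_ip, true_it, fitted_it = [], [], [], []
    halves: list[tuple[Optional[float], Optional[float]]] = []
    n_excluded = 0
    for profile in profiles:
        log = synthetic_cohort.simulate_decisions(
            profile, schedule, ts_cfg, rng, n_session_trials=n_session_trials
        )
        if log["abandon"].dropna().nunique() < 2:
            n_excluded += 1
            warnings.warn(f"participant {profile.pid}: constant choices, excluded")
            continue
        dataset = build_dataset(log, schedule, refit_cfg, rng, models=("tree_search",))
        fit = PersistenceLogit.from_dataframe(dataset, model="tree_search").fit()
        if not fit.converged or abs(fit.beta1) <= 1e-6:
            n_excluded += 1
            warnings.warn(f"participant {profile.pid}: fit flagged ({fit.flag}), excluded")
            continue
        true_ip.append(profile.ip_bias)
        fitted_ip.append(fit.indifference_point())
        true_it.append(profile.inv_temp)
        fitted_it.append(fit.beta1)
        halves.append(_split_half_ips(dataset))
    if len(true_ip) < 3:
        raise RecoverySkipped(
            "too few participants with identifiable fits (choices may be "
            "deterministic: no likelihood curvature to recover parameters from)"
        )
    true_ip = np.asarray(true_ip)
    fitted_ip = np.asarray(fitted_ip)
    true_it = np.asarray(true_it)
    fitted_it = np.asarray(fitted_it)

    valid_halves = [(a, b) for a, b in halves if a is not None and b is not None]
    icc = np.nan
    if len(valid_halves) >= 5:
        import pingouin as pg

        half_df = pd.DataFrame(
            {
                "pid": np.repeat(np.arange(len(valid_halves)), 2),
                "half": ["even", "odd"] * len(valid_halves),
                "ip": np.concatenate([np.array(h) for h in valid_halves]),
            }
        )
        icc_table = pg.intraclass_corr(
            data=half_df, targets="pid", raters="half", ratings="ip"
        )
        icc = float(icc_table.set_index("Type").loc["ICC(A,1)", "ICC"])

    return RecoveryReport(
        true_ip=true_ip,
        fitted_ip=fitted_ip,
        true_inv_temp=true_it,
        fitted_inv_temp=fitted_it,
        ip_pearson=float(stats.pearsonr(true_ip, fitted_ip)[0]),
        ip_spearman=float(stats.spearmanr(true_ip, fitted_ip)[0]),
        inv_temp_pearson=float(stats.pearsonr(true_it, fitted_it)[0]),
        inv_temp_spearman=float(stats.spearmanr(true_it, fitted_it)[0]),
        icc=icc,
        n_excluded=n_excluded,
    )
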