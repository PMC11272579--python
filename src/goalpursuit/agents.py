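"""Valuation models and agent policies for the goal-pursuit task.

Four models of increasing sophistication assign a value to each good:

* ``offer_max`` — the raw on-screen offer, ignoring net contents.
* ``myopic`` — maximises this trial's holdings: the current goal is worth the
  accumulated contents plus its offer, alternatives their raw offer.
* ``prospective`` — the proportion of net filled per trial if offers stayed
  constant: goal offer / remaining net for the goal, offer / net size for
  alternatives, with special rules for negative offers.
* ``tree_search`` — a Monte-Carlo planner that rolls offer trajectories
  forward with the task's true generative statistics and values each good as
  the negative mean number of trials until the net is full when committing to
  that good.

The subjective value of abandonment is the best alternative's value minus the
current goal's value; a softmax (logistic) policy turns it into an abandonment
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .task_engine import (
    BLOCK_COMPLETE,
    GOOD_LABELS,
    GenerativeParams,
    Schedule,
    TaskState,
    apply_choice,
    initial_state,
)

MODEL_NAMES = ("offer_max", "myopic", "prospective", "tree_search")


@dataclass(frozen=True)
class TreeSearchConfig:
    """Monte-Carlo rollout settings for the tree-search model.

    ``n_rollouts`` forward simulations per candidate good, each censored at
    ``max_horizon`` trials; ``params`` are the generative statistics used to
    evolve offers inside rollouts (the agent knows the true task statistics).
    """

    n_rollouts: int = 100
    max_horizon: int = 200
    params: GenerativeParams = GenerativeParams()

    def __post_init__(self) -> None:
        if self.n_rollouts < 1:
            raise ValueError("n_rollouts must be >= 1")
        if self.max_horizon < 1:
            raise ValueError("max_horizon must be >= 1")


@dataclass
class Valuation:
    """Per-good model values for one task state."""

    model_name: str
    values: np.ndarray  # 3 values, aligned with GOOD_LABELS
    goal_index: Optional[int]  # index of the current goal, None on trial 1

    @property
    def sv_abandon(self) -> Optional[float]:
        """Best alternative value minus current-goal value (None on trial 1)."""
        if self.goal_index is None:
            return None
        alts = np.delete(self.values, self.goal_index)
        return float(alts.max() - self.values[self.goal_index])

    @property
    def best_alternative_index(self) -> Optional[int]:
        if self.goal_index is None:
            return None
        candidates = [i for i in range(3) if i != self.goal_index]
        return max(candidates, key=lambda i: self.values[i])


def greedy_argmax(values: np.ndarray, rng: np.random.Generator) -> int:
    """Index of the maximal value, ties broken uniformly at random."""
    values = np.asarray(values, dtype=float)
    top = np.flatnonzero(values == values.max())
    if top.size == 1:
        return int(top[0])
    return int(rng.choice(top))


def _goal_index(state: TaskState) -> Optional[int]:
    if state.current_good is None:
        return None
    return GOOD_LABELS.index(state.current_good)


def offer_max_values(state: TaskState) -> Valuation:
    """Values are the raw offers, regardless of accumulated contents."""
    return Valuation("offer_max", np.array(state.offers, dtype=float), _goal_index(state))


def myopic_values(state: TaskState) -> Valuation:
    """Goal value = accumulated + goal offer; alternatives their raw offer.

    On the first trial of a block (no current goal, empty net) every good is a
    fresh choice, so the valuation degenerates to the raw offers.
    """
    goal = _goal_index(state)
    values = np.array(state.offers, dtype=float)
    if goal is not None:
        values[goal] = state.accumulated + state.offers[goal]
    return Valuation("myopic", values, goal)


def prospective_values(state: TaskState) -> Valuation:
    """Proportion-of-net valuation.

    Positive goal offer: offer / (net size - accumulated).  Positive
    alternative offer: offer / net size.  Negative alternative offer: the raw
    (negative) offer.  Negative goal offer: offer / accumulated, the (negative)
    proportion of progress lost; 0 when the net is empty, since the floor at
    zero means nothing can be lost.  On the first trial all goods are scored as
    fresh starts (offer / net size).
    """
    goal = _goal_index(state)
    net = state.net_size
    acc = state.accumulated
    values = np.empty(3, dtype=float)
    for i in range(3):
        offer = float(state.offers[i])
        if goal is not None and i == goal:
            if offer >= 0.0:
                values[i] = offer / (net - acc)
            elif acc > 0.0:
                values[i] = offer / acc
            else:
                values[i] = 0.0
        else:
            values[i] = offer / net if offer >= 0.0 else offer
    return Valuation("prospective", values, goal)


def _rollout_trials(
    offer0: float,
    accumulated0: float,
    net_size: float,
    params: GenerativeParams,
    n_rollouts: int,
    max_horizon: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Trials to fill the net across rollouts committed to one good.

    The first simulated trial applies the good's current offer (with the same
    forfeiture/floor semantics as a real choice); offers then evolve with the
    generative statistics, jumps referencing the offer level at rollout start.
    Rollouts not finished by ``max_horizon`` are censored at ``max_horizon``.
    """
    offers = np.full(n_rollouts, float(offer0))
    acc = np.full(n_rollouts, float(accumulated0))
    trials = np.full(n_rollouts, max_horizon, dtype=np.int64)
    alive = np.arange(n_rollouts)
    sd_walk = np.sqrt(params.walk_var)
    for t in range(1, max_horizon + 1):
        acc = np.maximum(0.0, acc + offers)
        done = acc >= net_size
        if done.any():
            trials[alive[done]] = t
            keep = ~done
            alive = alive[keep]
            acc = acc[keep]
            offers = offers[keep]
            if alive.size == 0:
                break
        if t == max_horizon:
            break
        n = offers.size
        u = rng.random(n)
        magnitude = rng.uniform(params.jump_lo, params.jump_hi, n)
        noise = rng.normal(0.0, sd_walk, n)
        up = u < params.p_jump_up
        down = (~up) & (u < params.p_jump_up + params.p_jump_down)
        offers = offers + noise
        offers[up] = offer0 + magnitude[up]
        offers[down] = offer0 - magnitude[down]
    return trials


def tree_search_values(
    state: TaskState,
    cfg: TreeSearchConfig,
    rng: np.random.Generator,
) -> Valuation:
    """Monte-Carlo commitment values: minus the mean trials to fill the net.

    For each candidate good the agent simulates choosing it now — forfeiting
    the net contents if it is not the current goal — and then committing to it
    on every subsequent trial while offers evolve stochastically.
    """
    goal = _goal_index(state)
    values = np.empty(3, dtype=float)
    for i in range(3):
        acc0 = state.accumulated if (goal is not None and i == goal) else 0.0
        trials = _rollout_trials(
            float(state.offers[i]),
            acc0,
            state.net_size,
            cfg.params,
            cfg.n_rollouts,
            cfg.max_horizon,
            rng,
        )
        values[i] = -float(trials.mean())
    return Valuation("tree_search", values, goal)


def compute_values(
    state: TaskState,
    model: str,
    cfg: Optional[TreeSearchConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Valuation:
    """Dispatch to the requested valuation model."""
    if model == "offer_max":
        return offer_max_values(state)
    if model == "myopic":
        return myopic_values(state)
    if model == "prospective":
        return prospective_values(state)
    if model == "tree_search":
        if cfg is None or rng is None:
            raise ValueError("tree_search requires a TreeSearchConfig and rng")
        return tree_search_values(state, cfg, rng)
    raise ValueError(f"unknown model: {model!r}")


def sigmoid(x) -> np.ndarray:
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


Policy = Union[str, tuple]


def run_session(
    schedule: Schedule,
    model: str,
    decide,
    rng: np.random.Generator,
    cfg: Optional[TreeSearchConfig] = None,
    n_session_trials: Optional[int] = None,
    participant: str = "agent",
) -> pd.DataFrame:
    """Play a session trial by trial with an arbitrary decision rule.

    ``decide(state, valuation, rng)`` returns ``(choice_index, p_abandon)``
    where ``p_abandon`` may be NaN (greedy policies, first trials).  The
    session ends after ``n_session_trials`` choices or when the schedule is
    exhausted, whichever comes first.  Returns a choice log with one row per
    trial, recording the pre-choice state and the model values.
    """
    rows = []
    session_trial = 0
    for block in schedule.blocks:
        state = initial_state(block)
        for t in range(1, block.n_trials + 1):
            if n_session_trials is not None and session_trial >= n_session_trials:
                return pd.DataFrame(rows)
            valuation = compute_values(state, model, cfg, rng)
            choice_idx, p_abandon = decide(state, valuation, rng)
            choice = GOOD_LABELS[choice_idx]
            nxt = apply_choice(state, choice)
            completed = nxt is BLOCK_COMPLETE
            session_trial += 1
            first = state.current_good is None
            goal = valuation.goal_index
            rows.append(
                {
                    "participant": participant,
                    "block": block.block_id,
                    "trial": t,
                    "session_trial": session_trial,
                    "net_size": block.net_size,
                    "accumulated": state.accumulated,
                    "progress": state.progress,
                    "current_good": state.current_good,
                    "trials_invested": state.trials_invested,
                    "offer_A": state.offers[0],
                    "offer_B": state.offers[1],
                    "offer_C": state.offers[2],
                    "choice": choice,
                    "abandon": np.nan if first else float(choice != state.current_good),
                    "p_abandon": p_abandon,
                    "V_goal": np.nan if goal is None else valuation.values[goal],
                    "V_altbest": np.nan
                    if goal is None
                    else valuation.values[valuation.best_alternative_index],
                    "completed_net": completed,
                    "model": model,
                }
            )
            if completed or t == block.n_trials:
                break
            state = replace(nxt, offers=block.offers[t])
    return pd.DataFrame(rows)


def simulate_agent(
    schedule: Schedule,
    model: str,
    policy: Policy = "greedy",
    cfg: Optional[TreeSearchConfig] = None,
    rng: Optional[np.random.Generator] = None,
    n_session_trials: Optional[int] = None,
    participant: str = "agent",
) -> pd.DataFrame:
    """Simulate an agent using one valuation model and a choice policy.

    ``policy`` is ``"greedy"`` (argmax value, uniform random tie-break) or
    ``("softmax", beta0, beta1)``: abandon with probability
    ``sigmoid(beta0 + beta1 * sv_abandon)`` and, when abandoning, pick the
    best alternative.  Softmax agents choose greedily on the first trial of a
    block, where persist/abandon is undefined.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model: {model!r}")
    if rng is None:
        rng = np.random.default_rng()

    if policy == "greedy":

        def decide(state, valuation, rng_):
            return greedy_argmax(valuation.values, rng_), np.nan

    elif isinstance(policy, tuple) and len(policy) == 3 and policy[0] == "softmax":
        beta0, beta1 = float(policy[1]), float(policy[2])

        def decide(state, valuation, rng_):
            if valuation.goal_index is None:
                return greedy_argmax(valuation.values, rng_), np.nan
            p_ab = float(sigmoid(beta0 + beta1 * valuation.sv_abandon))
            if rng_.random() < p_ab:
                return valuation.best_alternative_index, p_ab
            return valuation.goal_index, p_ab

    else:
        raise ValueError(f"unknown policy: {policy!r}")

    return run_session(
        schedule,
        model,
        decide,
        rng,
        cfg=cfg,
        n_session_trials=n_session_trials,
        participant=participant,
    )
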