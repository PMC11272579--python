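"""Engine for the incremental goal-pursuit ("fishing-net") task.

The task presents three goods on every trial, each with an offered quantity.
Choosing the good currently accumulating in the net adds the offer to the net
(a *persistence* choice); choosing a different good forfeits the accumulated
contents and restarts the net with the new good (an *abandonment* choice).
Filling the net earns one reward point and starts a new block with a fresh net
size and fresh offers.

Offers evolve as independent Gaussian random walks with occasional large jumps
relative to the block's starting offer, so pressure to abandon a goal can come
either from a collapse of the current goal's offer ("frustration") or from an
alternative becoming much more bountiful ("temptation").

Blocks are filtered by a tree-search acceptance simulation so that a planning
agent completes the net in more than ``accept_min`` and fewer than
``accept_max`` trials, keeping goals non-trivial yet feasible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical labels for the three goods.
GOOD_LABELS: tuple[str, str, str] = ("A", "B", "C")


class ScheduleGenerationError(RuntimeError):
    """Rejection sampling failed to produce enough accepted blocks."""


class _BlockComplete:
    """Singleton sentinel returned by :func:`apply_choice` when the net fills."""

    _instance: Optional["_BlockComplete"] = None

    def __new__(cls) -> "_BlockComplete":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "BLOCK_COMPLETE"


BLOCK_COMPLETE = _BlockComplete()


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the offer/net generative process.

    Defaults are the task's published schedule statistics: initial offers
    ~ N(6, 1) points, Gaussian walk variance 0.8 points^2 per trial, a 10%
    chance each of an upward or downward jump to the starting offer +/-
    U(3, 9) points, and net sizes uniform on [12, 72] points.
    """

    init_mean: float = 6.0
    init_var: float = 1.0
    walk_var: float = 0.8
    p_jump_up: float = 0.1
    p_jump_down: float = 0.1
    jump_lo: float = 3.0
    jump_hi: float = 9.0
    net_lo: float = 12.0
    net_hi: float = 72.0

    def __post_init__(self) -> None:
        if self.init_var < 0 or self.walk_var < 0:
            raise ValueError("variances must be non-negative")
        if not (0.0 <= self.p_jump_up <= 1.0 and 0.0 <= self.p_jump_down <= 1.0):
            raise ValueError("jump probabilities must lie in [0, 1]")
        if self.p_jump_up + self.p_jump_down > 1.0:
            raise ValueError("p_jump_up + p_jump_down must not exceed 1")
        if self.jump_lo > self.jump_hi:
            raise ValueError("jump_lo must not exceed jump_hi")
        if self.net_lo > self.net_hi:
            raise ValueError("net_lo must not exceed net_hi")


@dataclass
class Block:
    """One task block: a net to fill and a trial-by-trial offer matrix."""

    block_id: int
    net_size: float
    offers: np.ndarray  # shape (n_trials, 3)
    good_labels: tuple[str, str, str] = GOOD_LABELS

    def __post_init__(self) -> None:
        self.offers = np.asarray(self.offers, dtype=float)
        if self.offers.ndim != 2 or self.offers.shape[1] != 3:
            raise ValueError("offers must have shape (n_trials, 3)")
        if len(set(self.good_labels)) != 3:
            raise ValueError("good_labels must be 3 distinct labels")

    @property
    def n_trials(self) -> int:
        return self.offers.shape[0]

    @property
    def start_offers(self) -> np.ndarray:
        """Trial-1 offers; the reference point for jumps within the block."""
        return self.offers[0]


@dataclass
class TaskState:
    """The pre-choice state a valuation model sees on one trial.

    ``trials_invested`` counts consecutive prior choices of ``current_good``
    (0 on the first trial of a block, where ``current_good`` is None).
    """

    block_id: int
    trial_index: int  # 1-based within block
    net_size: float
    accumulated: float
    current_good: Optional[str]
    offers: np.ndarray  # current trial's 3 offers
    trials_invested: int = 0

    def __post_init__(self) -> None:
        self.offers = np.asarray(self.offers, dtype=float)
        if self.accumulated < 0:
            raise ValueError("accumulated net contents cannot be negative")

    @property
    def progress(self) -> float:
        """Goal progress: accumulated contents / net size, in [0, 1)."""
        return self.accumulated / self.net_size


def initial_state(block: Block) -> TaskState:
    """State on trial 1 of a block: empty net, no current goal."""
    return TaskState(
        block_id=block.block_id,
        trial_index=1,
        net_size=block.net_size,
        accumulated=0.0,
        current_good=None,
        offers=block.offers[0],
        trials_invested=0,
    )


def step_offers(
    offers: np.ndarray,
    start_offers: np.ndarray,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the three offers by one trial.

    Independently per option: with probability ``p_jump_up`` the next offer is
    the starting offer plus U(jump_lo, jump_hi); with probability
    ``p_jump_down`` it is the starting offer minus U(jump_lo, jump_hi);
    otherwise the walk continues, adding N(0, walk_var).  Offers are not
    clipped and may go negative.
    """
    offers = np.asarray(offers, dtype=float)
    start_offers = np.asarray(start_offers, dtype=float)
    u = rng.random(3)
    magnitude = rng.uniform(params.jump_lo, params.jump_hi, 3)
    noise = rng.normal(0.0, np.sqrt(params.walk_var), 3)
    up = u < params.p_jump_up
    down = (~up) & (u < params.p_jump_up + params.p_jump_down)
    nxt = offers + noise
    nxt = np.where(up, start_offers + magnitude, nxt)
    nxt = np.where(down, start_offers - magnitude, nxt)
    return nxt


def gen_block(
    params: GenerativeParams,
    n_trials: int,
    rng: np.random.Generator,
    block_id: int = 0,
) -> Block:
    """Draw one candidate block (no acceptance filtering).

    Net size ~ U(net_lo, net_hi) rounded to the nearest integer; trial-1
    offers i.i.d. N(init_mean, init_var); later rows via :func:`step_offers`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    net_size = float(np.round(rng.uniform(params.net_lo, params.net_hi)))
    offers = np.empty((n_trials, 3), dtype=float)
    offers[0] = rng.normal(params.init_mean, np.sqrt(params.init_var), 3)
    for t in range(1, n_trials):
        offers[t] = step_offers(offers[t - 1], offers[0], params, rng)
    return Block(block_id=block_id, net_size=net_size, offers=offers)


def apply_choice(
    state: TaskState,
    chosen: str,
    offer: Optional[float] = None,
):
    """Apply a choice to the state; return the next state or BLOCK_COMPLETE.

    Persisting adds the offer to the net; switching forfeits the accumulated
    contents and restarts the net with the chosen good's offer.  The net floor
    is zero (once empty, a negative offer changes nothing).  Reaching or
    exceeding the net size completes the block.

    The returned state keeps the current offers; the session driver installs
    the next trial's offers.
    """
    if chosen not in GOOD_LABELS:
        raise ValueError(f"unknown good label: {chosen!r}")
    idx = GOOD_LABELS.index(chosen)
    if offer is None:
        offer = float(state.offers[idx])
    persist = state.current_good is None or chosen == state.current_good
    if persist:
        new_acc = max(0.0, state.accumulated + offer)
        invested = state.trials_invested + 1
    else:
        new_acc = max(0.0, offer)
        invested = 1
    if new_acc >= state.net_size:
        return BLOCK_COMPLETE
    return replace(
        state,
        trial_index=state.trial_index + 1,
        accumulated=new_acc,
        current_good=chosen,
        trials_invested=invested,
    )


def accept_block(
    block: Block,
    ts_cfg,
    rng: np.random.Generator,
    accept_min: int = 3,
    accept_max: int = 15,
) -> tuple[bool, Optional[int]]:
    """Acceptance filter: simulate a greedy tree-search agent on the block.

    Returns ``(accepted, trials_to_complete)`` where a block is accepted iff
    the agent completes the net in strictly more than ``accept_min`` and
    strictly fewer than ``accept_max`` trials.  ``trials_to_complete`` is None
    when the net is never filled within the block's trials.
    """
    from .agents import greedy_argmax, tree_search_values

    state = initial_state(block)
    for t in range(1, block.n_trials + 1):
        valuation = tree_search_values(state, ts_cfg, rng)
        choice_idx = greedy_argmax(valuation.values, rng)
        nxt = apply_choice(state, GOOD_LABELS[choice_idx])
        if nxt is BLOCK_COMPLETE:
            return (accept_min < t < accept_max), t
        if t == block.n_trials:
            break
        state = replace(nxt, offers=block.offers[t])
    return False, None


@dataclass
class Schedule:
    """A sequence of accepted blocks plus the generative parameters used."""

    blocks: list[Block]
    params: GenerativeParams
    trials_to_complete: list[Optional[int]] = field(default_factory=list)
    seed: Optional[int] = None

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: block, trial, net_size, offer_A/B/C."""
        rows = []
        for block in self.blocks:
            for t in range(block.n_trials):
                rows.append(
                    {
                        "block": block.block_id,
                        "trial": t + 1,
                        "net_size": block.net_size,
                        "offer_A": block.offers[t, 0],
                        "offer_B": block.offers[t, 1],
                        "offer_C": block.offers[t, 2],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        """Write the schedule CSV plus a JSON sidecar with params and seed."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "params": dataclasses.asdict(self.params),
            "seed": self.seed,
            "trials_to_complete": self.trials_to_complete,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "Schedule":
        path = Path(path)
        df = pd.read_csv(path)
        params = GenerativeParams()
        seed = None
        ttc: list[Optional[int]] = []
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            params = GenerativeParams(**sidecar["params"])
            seed = sidecar.get("seed")
            ttc = sidecar.get("trials_to_complete", [])
        blocks = []
        for block_id, grp in df.groupby("block", sort=True):
            grp = grp.sort_values("trial")
            offers = grp[["offer_A", "offer_B", "offer_C"]].to_numpy()
            blocks.append(
                Block(
                    block_id=int(block_id),
                    net_size=float(grp["net_size"].iloc[0]),
                    offers=offers,
                )
            )
        return cls(blocks=blocks, params=params, trials_to_complete=ttc, seed=seed)

    def plot(self, block_id: int = 0, ax=None):
        """Plot one block's offer trajectories (one line per good)."""
        import matplotlib.pyplot as plt

        block = next(b for b in self.blocks if b.block_id == block_id)
        if ax is None:
            _, ax = plt.subplots()
        for i, label in enumerate(block.good_labels):
            ax.plot(np.arange(1, block.n_trials + 1), block.offers[:, i], label=label)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("trial")
        ax.set_ylabel("offer (points)")
        ax.set_title(f"block {block_id} (net = {block.net_size:g})")
        ax.legend()
        return ax


def gen_schedule(
    params: GenerativeParams,
    n_blocks: int,
    n_trials_per_block: int,
    ts_cfg,
    rng: np.random.Generator,
    max_reject: int = 10_000,
    accept_min: int = 3,
    accept_max: int = 15,
    seed: Optional[int] = None,
) -> Schedule:
    """Rejection-sample candidate blocks until ``n_blocks`` are accepted.

    Raises :class:`ScheduleGenerationError` if any slot exhausts
    ``max_reject`` candidates.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    blocks: list[Block] = []
    trials_to_complete: list[Optional[int]] = []
    for block_id in range(n_blocks):
        for _ in range(max_reject):
            candidate = gen_block(params, n_trials_per_block, rng, block_id=block_id)
            accepted, t_complete = accept_block(
                candidate, ts_cfg, rng, accept_min=accept_min, accept_max=accept_max
            )
            if accepted:
                blocks.append(candidate)
                trials_to_complete.append(t_complete)
                break
        else:
            raise ScheduleGenerationError(
                f"no acceptable block found in {max_reject} candidates"
            )
    return Schedule(
        blocks=blocks,
        params=params,
        trials_to_complete=trials_to_complete,
        seed=seed,
    )
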