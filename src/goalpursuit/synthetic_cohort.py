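"""Synthetic participants, choice data, attention data and lesion cohorts.

Real participants in this paradigm show (a) a positive persistence bias on
top of tree-search valuation, (b) progress-dependent attenuation of value
sensitivity that is stronger for alternative-goal value than for current-goal
value, (c) spatial report error that shrinks with trials invested for the
current-goal stimulus only, (d) a positive across-participant correlation
between goal-oriented attention and persistence bias, and (e), in a lesion
sample, reduced persistence bias when a designated ventromedial prefrontal
region is damaged.  This module generates cohorts with exactly that
statistical structure so that every downstream analysis is testable without
human data.

The attention/persistence coupling is implemented as a shared Gaussian latent
factor: a bivariate-normal copula with Pearson correlation
``2 * sin(pi * rho_s / 6)`` induces the target Spearman correlation ``rho_s``
between the (monotone) participant-level parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import agents
from .task_engine import GOOD_LABELS, Schedule


@dataclass
class ParticipantProfile:
    """Latent parameters of one synthetic participant.

    ``ip_bias`` is the persistence bias in units of tree-search abandonment
    value (trials); ``inv_temp`` the softmax inverse temperature;
    ``atten_cur``/``atten_alt`` the progress-attenuation slopes of the
    current-goal and alternative value weights (alternative attenuation is
    larger on average, producing the temptation/frustration asymmetry);
    the ``sp_*`` fields parameterise spatial report noise in normalized
    screen units, with ``sp_goal_slope`` <= 0 shrinking goal-stimulus error
    with trials invested.  ``latent_z`` is the shared factor coupling
    persistence and attention.
    """

    pid: str
    ip_bias: float
    inv_temp: float
    atten_cur: float
    atten_alt: float
    sp_base_sd: float
    sp_goal_slope: float
    sp_alt_slope: float
    sp_floor_sd: float
    rt_log_mean: float
    rt_log_sd: float
    rt_goal_shift: float
    latent_z: float

    def __post_init__(self) -> None:
        if self.inv_temp <= 0:
            raise ValueError("inv_temp must be positive")
        if self.sp_base_sd <= 0 or self.sp_floor_sd <= 0:
            raise ValueError("spatial noise scales must be positive")

    @property
    def attention_bias(self) -> float:
        """Latent goal-oriented attention strength (larger = more goal focus)."""
        return -self.sp_goal_slope


@dataclass
class CohortHyperparams:
    """Population distribution of participant parameters.

    Defaults emulate the published qualitative regime: a clearly positive
    mean persistence bias, log-normal inverse temperature, alternative-value
    attenuation exceeding current-goal attenuation, and an attention/
    persistence Spearman coupling of about 0.5.
    """

    n: int = 30
    ip_mean: float = 2.0
    ip_sd: float = 1.5
    inv_temp_log_mean: float = float(np.log(0.8))
    inv_temp_log_sd: float = 0.4
    target_rho: float = 0.5
    atten_cur_mean: float = 0.2
    atten_cur_sd: float = 0.1
    atten_gap_mean: float = 0.3
    atten_gap_sd: float = 0.1
    sp_base_sd: float = 0.15
    sp_floor_sd: float = 0.02
    sp_goal_slope_mean: float = -0.010
    sp_goal_slope_sd: float = 0.004
    sp_alt_slope_sd: float = 0.002
    rt_log_mean: float = float(np.log(0.9))
    rt_log_sd: float = 0.25
    rt_goal_shift_mean: float = -0.08

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        if not -1.0 < self.target_rho < 1.0:
            raise ValueError("|target_rho| must be < 1")


def gen_cohort(h: CohortHyperparams, rng: np.random.Generator) -> list[ParticipantProfile]:
    """Draw a cohort whose attention and persistence parameters are coupled.

    ``ip_bias`` loads on latent z1 and the goal-stimulus error slope on z2,
    with corr(z1, z2) chosen so the induced Spearman correlation between
    ``attention_bias`` and ``ip_bias`` approximates ``target_rho``.
    """
    rho_pearson = 2.0 * np.sin(np.pi * h.target_rho / 6.0)
    cov = np.array([[1.0, rho_pearson], [rho_pearson, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=h.n)
    profiles = []
    for i in range(h.n):
        z1, z2 = z[i]
        atten_cur = float(np.clip(rng.normal(h.atten_cur_mean, h.atten_cur_sd), 0.0, 1.0))
        gap = max(0.0, rng.normal(h.atten_gap_mean, h.atten_gap_sd))
        profiles.append(
            ParticipantProfile(
                pid=f"p{i:03d}",
                ip_bias=float(h.ip_mean + h.ip_sd * z1),
                inv_temp=float(np.exp(rng.normal(h.inv_temp_log_mean, h.inv_temp_log_sd))),
                atten_cur=atten_cur,
                atten_alt=float(np.clip(atten_cur + gap, 0.0, 1.0)),
                sp_base_sd=h.sp_base_sd,
                sp_goal_slope=float(min(0.0, h.sp_goal_slope_mean - h.sp_goal_slope_sd * z2)),
                sp_alt_slope=float(rng.normal(0.0, h.sp_alt_slope_sd)),
                sp_floor_sd=h.sp_floor_sd,
                rt_log_mean=h.rt_log_mean,
                rt_log_sd=h.rt_log_sd,
                rt_goal_shift=h.rt_goal_shift_mean,
                latent_z=float(z1),
            )
        )
    return profiles


def simulate_decisions(
    profile: ParticipantProfile,
    schedule: Schedule,
    ts_cfg: agents.TreeSearchConfig,
    rng: np.random.Generator,
    n_session_trials: Optional[int] = 300,
) -> pd.DataFrame:
    """Simulate one participant's session under the biased softmax rule.

    On non-first trials the abandonment propensity is

        SV = inv_temp * [(1 - atten_alt * p) * V_altbest
                         - (1 - atten_cur * p) * V_goal - ip_bias]

    with p the goal progress and V the tree-search values; abandonment occurs
    with probability sigmoid(SV) and selects the best alternative.  First
    trials of a block are greedy over tree-search values.  With both
    attenuations at zero this is exactly the logistic model the fitting
    module estimates, with beta1 = inv_temp and IP = ip_bias.
    """

    def decide(state, valuation, rng_):
        if valuation.goal_index is None:
            return agents.greedy_argmax(valuation.values, rng_), np.nan
        p = state.progress
        v_goal = valuation.values[valuation.goal_index]
        v_alt = valuation.values[valuation.best_alternative_index]
        sv = profile.inv_temp * (
            (1.0 - profile.atten_alt * p) * v_alt
            - (1.0 - profile.atten_cur * p) * v_goal
            - profile.ip_bias
        )
        p_ab = float(agents.sigmoid(sv))
        if rng_.random() < p_ab:
            return valuation.best_alternative_index, p_ab
        return valuation.goal_index, p_ab

    return agents.run_session(
        schedule,
        "tree_search",
        decide,
        rng,
        cfg=ts_cfg,
        n_session_trials=n_session_trials,
        participant=profile.pid,
    )


def simulate_attention(
    profile: ParticipantProfile,
    choice_log: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate the interleaved spatial-report log for one choice log.

    Per trial, each of the three stimuli appears at a uniform random location
    on the unit square; the report adds isotropic Gaussian noise whose s.d.
    declines with trials invested for the current-goal stimulus
    (``sp_goal_slope``) and is essentially flat for alternatives, floored at
    ``sp_floor_sd``.  Reaction times are log-normal with an additive negative
    shift for the goal stimulus.  First trials of blocks (no goal yet) are
    emitted with ``first_trial=True`` and excluded from analysis views.
    """
    rows = []
    for _, row in choice_log.iterrows():
        first = pd.isna(row["current_good"])
        invested = int(row["trials_invested"])
        for label in GOOD_LABELS:
            is_goal = (not first) and label == row["current_good"]
            status = "none" if first else ("goal" if is_goal else "alt")
            slope = profile.sp_goal_slope if is_goal else profile.sp_alt_slope
            sd = max(profile.sp_floor_sd, profile.sp_base_sd + slope * invested)
            true_xy = rng.random(2)
            reported_xy = true_xy + rng.normal(0.0, sd, 2)
            rt = float(np.exp(rng.normal(profile.rt_log_mean, profile.rt_log_sd)))
            if is_goal:
                rt = max(0.05, rt + profile.rt_goal_shift)
            rows.append(
                {
                    "pid": row["participant"],
                    "block": row["block"],
                    "trial": row["trial"],
                    "stimulus": label,
                    "stimulus_status": status,
                    "first_trial": first,
                    "trials_invested": invested,
                    "true_x": true_xy[0],
                    "true_y": true_xy[1],
                    "reported_x": reported_xy[0],
                    "reported_y": reported_xy[1],
                    "error": float(np.linalg.norm(reported_xy - true_xy)),
                    "rt": rt,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class LesionCohort:
    """Binary lesion maps on a shared voxel grid, with behavioural biases."""

    maps: np.ndarray  # (n_patients, nx, ny, nz) boolean
    biases: np.ndarray  # persistence bias per patient
    roi_center: tuple[int, int, int]
    roi_radius_vox: float
    voxel_size_mm: float = 2.4

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        if self.maps.dtype != bool:
            uniq = np.unique(self.maps)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("lesion maps must be binary")
            self.maps = self.maps.astype(bool)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.maps.shape[0] != self.biases.size:
            raise ValueError("one bias per patient required")

    @property
    def n_patients(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]

    def save(self, directory) -> None:
        """Write one NIfTI volume per patient plus a cohort.csv of biases."""
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        for i in range(self.n_patients):
            img = nib.Nifti1Image(self.maps[i].astype(np.uint8), affine)
            nib.save(img, directory / f"lesion_{i:03d}.nii")
        pd.DataFrame(
            {"patient": np.arange(self.n_patients), "bias": self.biases}
        ).to_csv(directory / "cohort.csv", index=False)

    @classmethod
    def load(
        cls,
        directory,
        roi_center: tuple[int, int, int],
        roi_radius_vox: float = 3.0,
    ) -> "LesionCohort":
        import nibabel as nib

        directory = Path(directory)
        cohort = pd.read_csv(directory / "cohort.csv")
        maps = []
        for i in cohort["patient"]:
            img = nib.load(directory / f"lesion_{int(i):03d}.nii")
            maps.append(np.asarray(img.dataobj) > 0)
        return cls(
            maps=np.stack(maps),
            biases=cohort["bias"].to_numpy(),
            roi_center=roi_center,
            roi_radius_vox=roi_radius_vox,
        )


def _grow_lesion(
    seed_voxel: tuple[int, int, int],
    size: int,
    grid_dims: tuple[int, int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow a contiguous (face-connected) random blob from a seed voxel."""
    grid = np.zeros(grid_dims, dtype=bool)
    grid[seed_voxel] = True

    def neighbours(v):
        x, y, z = v
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nx_, ny_, nz_ = x + dx, y + dy, z + dz
            if 0 <= nx_ < grid_dims[0] and 0 <= ny_ < grid_dims[1] and 0 <= nz_ < grid_dims[2]:
                yield (nx_, ny_, nz_)

    # frontier list may hold duplicates / already-filled entries; they are
    # skipped on draw, which keeps growth O(size) and deterministic under rng
    frontier = list(neighbours(seed_voxel))
    n_filled = 1
    while n_filled < size and frontier:
        j = int(rng.integers(len(frontier)))
        pick = frontier[j]
        frontier[j] = frontier[-1]
        frontier.pop()
        if grid[pick]:
            continue
        grid[pick] = True
        n_filled += 1
        frontier.extend(v for v in neighbours(pick) if not grid[v])
    return grid


def gen_lesion_cohort(
    n_patients: int = 23,
    grid_dims: tuple[int, int, int] = (20, 24, 20),
    roi_center: tuple[int, int, int] = (10, 17, 6),
    roi_radius_vox: float = 3.0,
    effect_delta: float = 3.0,
    noise_sd: float = 1.0,
    lesion_size_range: tuple[int, int] = (50, 400),
    ip_mean: float = 2.0,
    n_roi_seeded: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> LesionCohort:
    """Generate a lesion cohort with an implanted region-behaviour effect.

    Each patient receives one random contiguous lesion; the first
    ``n_roi_seeded`` lesions are seeded at ``roi_center`` so the designated
    region is reliably damaged in a subset of the cohort.  Behavioural bias:
    ``ip_mean - effect_delta * [lesion overlaps ROI ball] + N(0, noise_sd)``.
    With ``effect_delta=0`` the cohort is an exact null.
    """
    if rng is None:
        rng = np.random.default_rng()
    center = np.asarray(roi_center)
    if (center < 0).any() or (center >= np.asarray(grid_dims)).any():
        raise ValueError("roi_center must lie inside the grid")
    if (center - roi_radius_vox < 0).any() or (
        center + roi_radius_vox >= np.asarray(grid_dims)
    ).any():
        raise ValueError("ROI ball must fit inside the grid")
    lo, hi = lesion_size_range
    if lo < 1 or hi < lo or hi > int(np.prod(grid_dims)):
        raise ValueError("impossible lesion size range for this grid")
    from .lesion_mapping import roi_mask

    ball = roi_mask(grid_dims, roi_center, roi_radius_vox)
    maps = np.zeros((n_patients,) + tuple(grid_dims), dtype=bool)
    biases = np.empty(n_patients)
    for i in range(n_patients):
        if i < n_roi_seeded:
            seed_voxel = tuple(int(c) for c in roi_center)
        else:
            seed_voxel = tuple(int(rng.integers(d)) for d in grid_dims)
        size = int(rng.integers(lo, hi + 1))
        maps[i] = _grow_lesion(seed_voxel, size, tuple(grid_dims), rng)
        overlaps = bool((maps[i] & ball).any())
        biases[i] = ip_mean - effect_delta * overlaps + rng.normal(0.0, noise_sd)
    return LesionCohort(
        maps=maps,
        biases=biases,
        roi_center=tuple(int(c) for c in roi_center),
        roi_radius_vox=roi_radius_vox,
    )


def profiles_to_yaml(profiles: Sequence[ParticipantProfile], path) -> None:
    import yaml

    Path(path).write_text(
        yaml.safe_dump([dataclasses.asdict(p) for p in profiles], sort_keys=False)
    )


def profiles_from_yaml(path) -> list[ParticipantProfile]:
    import yaml

    return [ParticipantProfile(**d) for d in yaml.safe_load(Path(path).read_text())]
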