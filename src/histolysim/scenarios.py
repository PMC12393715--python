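"""Scenario construction, parameter schedules, and experiment drivers.

A scenario describes the initial layout (muscle-unit belts, hemocytes, fat
body cells), the hemocyte motility heterogeneity, and an optional
"stabilization" operation: a piecewise-linear parameter ramp over the
30–50 hAPF window (confinement walls, propulsion, friction, or adhesion)
whose magnitude can be calibrated by linear regression to reach a target
decrease in muscle-unit speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .mechanics import (HAPF_ORIGIN, STEPS_PER_HOUR, STEPS_PER_MIN, Kind,
                        ModelParams, MuscleState, SUBTYPE_CODE, World)

__all__ = [
    "FatMode", "Heterogeneity", "Stabilization", "ScenarioConfig",
    "Ramp", "ParamSchedule", "EffectiveParams", "Trajectory",
    "CalibrationResult", "CalibrationError",
    "build_initial_world", "assign_heterogeneity", "make_schedule",
    "schedule_value", "run_trial", "run_trials", "run_experiment",
    "calibrate_stabilization",
]

#: stabilization ramp window in steps (30–50 hAPF)
STAB_WINDOW = (129_600, 273_600)
#: belt width [m] (kept fixed under field rescaling)
BELT_WIDTH = 1.0e-4


class FatMode(str, Enum):
    NONE = "none"
    INITIAL = "initial"
    FLOATING = "floating"


class Heterogeneity(str, Enum):
    HOMOG = "homog"
    SPEED_HET = "speed_het"
    TURN_HET = "turn_het"


class Stabilization(str, Enum):
    NONE = "none"
    CONFINE = "confine"
    PROPULSION_DOWN = "propulsion_down"
    FRICTION_UP = "friction_up"
    ADHESION_HF_UP = "adhesion_hf_up"
    ADHESION_HH_UP = "adhesion_hh_up"


#: reference ramp endpoints of the five operations
STAB_DEFAULT_MAGNITUDE = {
    Stabilization.CONFINE: 90.0e-6,          # wall thickness per wall [m]
    Stabilization.PROPULSION_DOWN: 0.80,     # hemocyte propulsion multiplier
    Stabilization.FRICTION_UP: 3.9e-2,       # final friction [N s/m]
    Stabilization.ADHESION_HF_UP: 4.0e-9,    # final a_HF [N]
    Stabilization.ADHESION_HH_UP: 2.2e-9,    # final a_HH [N]
}

#: reference population sizes on the full 600-um field
N_MUSCLE_FULL = 900
N_HEMOCYTE_FULL = 800
N_FAT_INITIAL_FULL = 90
N_FAT_FLOATING_FULL = 70


@dataclass(frozen=True)
class ScenarioConfig:
    """A simulation condition.

    ``scale`` rescales the field side; particle counts scale with
    ``scale**2`` so local densities (and hence per-particle statistics) are
    preserved, while belt width and particle radii stay fixed.
    """

    fat_mode: FatMode = FatMode.FLOATING
    heterogeneity: Heterogeneity = Heterogeneity.HOMOG
    stabilization: Stabilization = Stabilization.NONE
    magnitude: float | None = None
    scale: float = 1.0
    n_trials: int = 6
    seed: int = 0
    steps: int | None = None
    params: ModelParams = field(default_factory=ModelParams)
    fat_r_min: float = 18.0e-6
    fat_r_max: float = 28.0e-6

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.field_size < 2 * BELT_WIDTH:
            raise ValueError("field too small for the two muscle belts")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def field_size(self) -> float:
        return self.params.field_size * self.scale

    @property
    def n_muscle_per_belt(self) -> int:
        return max(1, round(N_MUSCLE_FULL / 2 * self.scale ** 2))

    @property
    def n_muscle(self) -> int:
        return 2 * self.n_muscle_per_belt

    @property
    def n_hemocyte(self) -> int:
        return max(1, round(N_HEMOCYTE_FULL * self.scale ** 2))

    @property
    def n_fat(self) -> int:
        if self.fat_mode == FatMode.NONE:
            return 0
        full = (N_FAT_INITIAL_FULL if self.fat_mode == FatMode.INITIAL
                else N_FAT_FLOATING_FULL)
        return max(1, round(full * self.scale ** 2))

    @property
    def steps_total(self) -> int:
        return self.steps if self.steps is not None else self.params.steps_total


def _belt_bounds(L: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Two vertical belts of fixed width centered at L/4 and 3L/4; the
    inter-belt gap equals the wrap-around gap (200 um at full scale)."""
    h = BELT_WIDTH / 2
    return ((L / 4 - h, L / 4 + h), (3 * L / 4 - h, 3 * L / 4 + h))


def build_initial_world(config: ScenarioConfig, rng=None) -> World:
    """Construct the initial world: uneaten muscle units uniform over the
    two belts (half in each), hemocytes uniform over the belt complement,
    and fat body cells per the fat mode (INITIAL: full radius outside the
    belts; FLOATING: radius zero anywhere).  Initial overlaps are allowed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p = config.params
    L = config.field_size
    (b0, b1) = _belt_bounds(L)
    n_m, n_h, n_f = config.n_muscle, config.n_hemocyte, config.n_fat
    n = n_m + n_h + n_f

    pos = np.empty((n, 2))
    half = config.n_muscle_per_belt
    pos[:half, 0] = rng.uniform(b0[0], b0[1], half)
    pos[half:n_m, 0] = rng.uniform(b1[0], b1[1], n_m - half)
    pos[:n_m, 1] = rng.uniform(0, L, n_m)

    def outside_belts(count: int) -> np.ndarray:
        xs = np.empty(count)
        got = 0
        while got < count:
            cand = rng.uniform(0, L, count - got)
            ok = ~(((cand >= b0[0]) & (cand < b0[1]))
                   | ((cand >= b1[0]) & (cand < b1[1])))
            take = cand[ok]
            xs[got:got + take.size] = take
            got += take.size
        return xs

    pos[n_m:n_m + n_h, 0] = outside_belts(n_h)
    pos[n_m:n_m + n_h, 1] = rng.uniform(0, L, n_h)

    kind = np.concatenate([np.full(n_m, Kind.MUSCLE),
                           np.full(n_h, Kind.HEMOCYTE),
                           np.full(n_f, Kind.FAT)]).astype(np.int8)
    radius = np.concatenate([np.full(n_m, p.r_muscle),
                             np.full(n_h, p.r_hemocyte),
                             np.zeros(n_f)])
    radius_max = radius.copy()
    if n_f:
        R = np.linspace(config.fat_r_min, config.fat_r_max, n_f)
        radius_max[n_m + n_h:] = R
        if config.fat_mode == FatMode.INITIAL:
            radius[n_m + n_h:] = R
            pos[n_m + n_h:, 0] = outside_belts(n_f)
        else:
            pos[n_m + n_h:, 0] = rng.uniform(0, L, n_f)
        pos[n_m + n_h:, 1] = rng.uniform(0, L, n_f)

    ang = rng.uniform(0, 2 * math.pi, n)
    head = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    state = np.where(kind == Kind.MUSCLE, int(MuscleState.UNEATEN), -1)
    host = np.full(n, -1)
    v = np.concatenate([np.zeros(n_m), np.full(n_h, p.v_hemocyte),
                        np.full(n_f, p.v_fat)])
    pt = np.full(n, p.p_turn)

    params = p.with_(field_size=L) if config.scale != 1.0 else p
    world = World(params, pos, head, radius, radius_max, kind, state, host,
                  v, pt, rng=rng,
                  fat_floating=config.fat_mode == FatMode.FLOATING)
    return world


#: motility profiles of the hemocyte subtypes (v [N], p_turn)
HET_PROFILES = {
    "standard": (5.0e-9, 0.005),
    "slow": (1.0e-9, 0.005),
    "fast": (9.0e-9, 0.005),
    "meander": (5.0e-9, 0.009),
    "straight": (5.0e-9, 0.001),
}


def assign_heterogeneity(world: World, mode: Heterogeneity, rng=None) -> World:
    """Assign hemocyte motility subtypes.

    HOMOG: all standard (v = 5 nN, p_turn = 0.005).  SPEED_HET: a random
    half slow (1 nN) and half fast (9 nN).  TURN_HET: a random half meander
    (p_turn = 0.009) and half straight (0.001).  Population means equal the
    homogeneous values.  Odd counts split floor/ceil.
    """
    rng = rng if rng is not None else world.rng
    hem = np.flatnonzero(world.kind == Kind.HEMOCYTE)
    if mode == Heterogeneity.HOMOG:
        pairs = [("standard", hem)]
    else:
        perm = rng.permutation(hem)
        lo, hi = perm[:hem.size // 2], perm[hem.size // 2:]
        if mode == Heterogeneity.SPEED_HET:
            pairs = [("slow", lo), ("fast", hi)]
        else:
            pairs = [("meander", lo), ("straight", hi)]
    for label, idx in pairs:
        v, pt = HET_PROFILES[label]
        world.v_base[idx] = v
        world.p_turn[idx] = pt
        world.subtype[idx] = SUBTYPE_CODE[label]
    return world


# -- time-varying parameters ---------------------------------------------------


@dataclass(frozen=True)
class Ramp:
    """Piecewise-linear time course, quantized to minute boundaries."""

    start_step: int
    end_step: int
    start_value: float
    end_value: float

    def value(self, step: int) -> float:
        q = (step // STEPS_PER_MIN) * STEPS_PER_MIN
        if q <= self.start_step:
            return self.start_value
        if q >= self.end_step:
            return self.end_value
        f = (q - self.start_step) / (self.end_step - self.start_step)
        return self.start_value + f * (self.end_value - self.start_value)


@dataclass(frozen=True)
class ParamSchedule:
    mu: Ramp | None = None
    v_mult: Ramp | None = None
    a_HF: Ramp | None = None
    a_HH: Ramp | None = None
    wall: Ramp | None = None


class EffectiveParams(NamedTuple):
    mu: float
    v_mult: float
    a_HF: float
    a_HH: float
    wall_w: float
    walled: bool


def make_schedule(stabilization: Stabilization,
                  magnitude: float | None = None,
                  window: tuple[int, int] = STAB_WINDOW,
                  params: ModelParams | None = None) -> ParamSchedule:
    p = params or ModelParams()
    if stabilization == Stabilization.NONE:
        return ParamSchedule()
    m = magnitude if magnitude is not None \
        else STAB_DEFAULT_MAGNITUDE[stabilization]
    a, b = window
    if stabilization == Stabilization.CONFINE:
        return ParamSchedule(wall=Ramp(a, b, 0.0, m))
    if stabilization == Stabilization.PROPULSION_DOWN:
        return ParamSchedule(v_mult=Ramp(a, b, 1.0, m))
    if stabilization == Stabilization.FRICTION_UP:
        return ParamSchedule(mu=Ramp(a, b, p.mu, m))
    if stabilization == Stabilization.ADHESION_HF_UP:
        return ParamSchedule(a_HF=Ramp(a, b, p.a_HF, m))
    if stabilization == Stabilization.ADHESION_HH_UP:
        return ParamSchedule(a_HH=Ramp(a, b, p.a_HH, m))
    raise ValueError(stabilization)


def schedule_value(schedule: ParamSchedule, step: int,
                   params: ModelParams | None = None) -> EffectiveParams:
    """Effective parameter set at ``step`` (minute-quantized ramps; Table
    defaults outside any ramp).  The field boundary switches to walled while
    the confinement thickness is positive."""
    p = params or ModelParams()
    mu = schedule.mu.value(step) if schedule.mu else p.mu
    vm = schedule.v_mult.value(step) if schedule.v_mult else 1.0
    ahf = schedule.a_HF.value(step) if schedule.a_HF else p.a_HF
    ahh = schedule.a_HH.value(step) if schedule.a_HH else p.a_HH
    w = schedule.wall.value(step) if schedule.wall else 0.0
    return EffectiveParams(mu, vm, ahf, ahh, w, w > 0.0)


# -- trial driver --------------------------------------------------------------


@dataclass
class Trajectory:
    """Minute-sampled state of one trial (positions in micrometres)."""

    steps: np.ndarray
    pos_um: np.ndarray          # (S, N, 2) float32
    state: np.ndarray           # (S, N) int8; -1 for non-muscle
    host: np.ndarray            # (S, N) int32
    radius_um: np.ndarray       # (S, N) float32
    kind: np.ndarray            # (N,) int8
    subtype: np.ndarray         # (N,) int8
    field_um: float
    seed: int
    sample_every: int = STEPS_PER_MIN

    @property
    def hapf(self) -> np.ndarray:
        return HAPF_ORIGIN + self.steps / STEPS_PER_HOUR

    @property
    def n_samples(self) -> int:
        return len(self.steps)

    def index_at(self, hapf: float) -> int:
        i = int(np.argmin(np.abs(self.hapf - hapf)))
        if abs(self.hapf[i] - hapf) > 1e-6:
            raise ValueError(f"no sample at {hapf} hAPF")
        return i

    def positions_at(self, hapf: float, kind: Kind | None = None) -> np.ndarray:
        i = self.index_at(hapf)
        if kind is None:
            return np.asarray(self.pos_um[i], float)
        return np.asarray(self.pos_um[i][self.kind == int(kind)], float)

    def to_dataframe(self, trial: int = 0) -> pd.DataFrame:
        from .mechanics import SUBTYPE_LABELS
        S, N = self.state.shape
        rows = {
            "trial": np.repeat(trial, S * N),
            "step": np.repeat(self.steps, N),
            "hapf": np.round(np.repeat(self.hapf, N), 6),
            "id": np.tile(np.arange(N), S),
            "kind": np.tile(np.array(["muscle", "hemocyte", "fat"])[self.kind], S),
            "state": np.where(self.state.ravel() == 1, "eaten",
                              np.where(self.state.ravel() == 0, "uneaten", "")),
            "host_id": self.host.ravel(),
            "x_um": np.round(self.pos_um[:, :, 0].ravel().astype(float), 4),
            "y_um": np.round(self.pos_um[:, :, 1].ravel().astype(float), 4),
            "r_um": np.round(self.radius_um.ravel().astype(float), 4),
            "subtype": np.tile(np.array(SUBTYPE_LABELS)[self.subtype], S),
        }
        return pd.DataFrame(rows)


def run_trial(config: ScenarioConfig, seed: int,
              sample_every: int = STEPS_PER_MIN,
              record_from: int = 0) -> Trajectory:
    """Run one trial to ``config.steps_total`` steps, sampling every
    ``sample_every`` steps (must be a multiple of the minute cadence)."""
    if sample_every % STEPS_PER_MIN:
        raise ValueError("sample_every must be a multiple of 120 steps")
    rng = np.random.default_rng(seed)
    world = build_initial_world(config, rng)
    assign_heterogeneity(world, config.heterogeneity, rng)
    schedule = make_schedule(config.stabilization, config.magnitude,
                             params=config.params)
    total = config.steps_total

    samples, poss, states, hosts, radii = [], [], [], [], []

    def record() -> None:
        samples.append(world.step_count)
        poss.append((world.positions * 1e6).astype(np.float32))
        states.append(world.state.copy())
        hosts.append(world.host.copy())
        radii.append((world.radius * 1e6).astype(np.float32))

    while True:
        s = world.step_count
        if s % STEPS_PER_MIN == 0:
            world.update_fat_radii()
            eff = schedule_value(schedule, s, config.params)
            world.mu_eff = eff.mu
            world.v_mult = eff.v_mult
            world.a_HF_eff = eff.a_HF
            world.a_HH_eff = eff.a_HH
            world.wall_w = eff.wall_w
            world.walled = eff.walled
        if s >= record_from and s % sample_every == 0:
            record()
        if s >= total:
            break
        world.advance(min(STEPS_PER_MIN - s % STEPS_PER_MIN, total - s))

    return Trajectory(np.array(samples), np.array(poss), np.array(states),
                      np.array(hosts), np.array(radii), world.kind.copy(),
                      world.subtype.copy(), world.params.field_size * 1e6,
                      seed, sample_every)


def run_trials(config: ScenarioConfig,
               sample_every: int = STEPS_PER_MIN,
               record_from: int = 0) -> list[Trajectory]:
    """Run ``config.n_trials`` independent trials (trial t uses seed
    ``config.seed + t``)."""
    return [run_trial(replace(config, seed=config.seed + t),
                      config.seed + t, sample_every, record_from)
            for t in range(config.n_trials)]


def run_experiment(config: ScenarioConfig, metrics: dict | None = None,
                   **kw) -> pd.DataFrame:
    """Run all trials and evaluate ``metrics`` (name -> f(Trajectory)) per
    trial; returns a tidy table with one row per trial."""
    trajs = run_trials(config, **kw)
    rows = []
    for t, traj in enumerate(trajs):
        row = {"trial": t, "seed": traj.seed}
        for name, fn in (metrics or {}).items():
            row[name] = fn(traj)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["trajectories"] = trajs
    return df


# -- stabilization calibration -------------------------------------------------


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationResult:
    operation: Stabilization
    magnitude: float            # x* with predicted retention = target
    slope: float
    intercept: float
    target: float
    table: pd.DataFrame         # magnitude, trial, retention_pct

    def predicted(self, x: float) -> float:
        return self.intercept + self.slope * x


def calibrate_stabilization(operation: Stabilization,
                            magnitudes: Sequence[float],
                            trials_per_magnitude: int,
                            config: ScenarioConfig,
                            base_seed: int | None = None,
                            target: float = 80.0,
                            response=None) -> CalibrationResult:
    """Linear-regression calibration of a stabilization operation.

    For each swept magnitude, runs trials of the scenario with the ramp at
    that magnitude and computes the speed-retention response: the median
    muscle-unit speed at 50 hAPF as a percentage of that at 30 hAPF.
    Ordinary least squares of the per-trial responses on magnitude gives
    the magnitude at which the predicted response equals ``target``
    (percent; the reference operations were tuned to 80, i.e. a one-fifth
    slowdown).
    """
    from .experiments import speed_retention_percent

    if len(magnitudes) < 2:
        raise ValueError("need at least two magnitudes")
    base_seed = config.seed if base_seed is None else base_seed
    resp = response or (lambda traj: speed_retention_percent([traj]))
    rows = []
    for m in magnitudes:
        cfg = replace(config, stabilization=operation, magnitude=float(m),
                      n_trials=trials_per_magnitude, seed=base_seed)
        for t, traj in enumerate(run_trials(cfg)):
            rows.append({"magnitude": float(m), "trial": t,
                         "retention_pct": float(resp(traj))})
    table = pd.DataFrame(rows)
    x = table["magnitude"].to_numpy()
    y = table["retention_pct"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(y) < 1e-12 or slope == 0 or not np.isfinite(slope):
        raise CalibrationError("zero-slope regression; responses do not "
                               "depend on the swept magnitude")
    x_star = (target - intercept) / slope
    return CalibrationResult(operation, float(x_star), float(slope),
                             float(intercept), target, table)
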