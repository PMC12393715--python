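"""Agent-based physics core for pupal muscle remodeling.

Three kinds of soft circular particles live in a square field with periodic
boundaries: stationary muscle units, self-propelled hemocytes, and large fat
body cells.  Motion is overdamped (velocity proportional to net force over a
friction coefficient) and integrated with an explicit Euler scheme.  Contact
produces a linear-spring repulsion proportional to the overlap length plus a
pairwise adhesion whose strength depends on the particle kinds; phagocytosis
is modeled as an outsized adhesion between a hemocyte and an uneaten muscle
unit, which then becomes "eaten" and follows its host.

All internal quantities are SI (m, s, N).  Reporting layers convert to
micrometres and minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from . import _kernels

__all__ = [
    "Kind",
    "MuscleState",
    "ModelParams",
    "MotilityProfile",
    "ParticleState",
    "World",
    "SimulationBlowupError",
    "contact_set",
    "adhesion_coefficient",
    "pairwise_force",
    "wall_force",
    "turning_update",
    "phagocytosis_update",
    "bond_break_update",
    "fat_radius_update",
    "step",
]

#: integration steps per simulated minute / hour (dt = 0.5 s)
STEPS_PER_MIN = 120
STEPS_PER_HOUR = 7200
#: simulation starts at 12 h after puparium formation
HAPF_ORIGIN = 12.0
#: step at which fat body cells may start floating (14 hAPF)
FAT_FLOAT_START_STEP = 14_400
#: fat body radius increment per minute once floating [m]
FAT_RADIUS_INCREMENT = 0.383e-6


def hapf_to_step(hapf: float) -> int:
    return int(round((hapf - HAPF_ORIGIN) * STEPS_PER_HOUR))


def step_to_hapf(step: int) -> float:
    return HAPF_ORIGIN + step / STEPS_PER_HOUR


class Kind(IntEnum):
    MUSCLE = 0
    HEMOCYTE = 1
    FAT = 2


class MuscleState(IntEnum):
    UNEATEN = 0
    EATEN = 1


class SimulationBlowupError(RuntimeError):
    """Raised when a particle position becomes non-finite."""


@dataclass(frozen=True)
class ModelParams:
    """Mechanical constants and integration settings.

    Defaults are the reference parameter set of the model: friction
    ``mu`` [N s/m], repulsion stiffness ``k`` [N/m], particle radii [m],
    intercellular adhesion strengths ``a_HF``/``a_HH``/``a_FF`` [N], the
    phagocytosis adhesion ``a_E`` [N], time step ``dt`` [s], field side
    length [m], and total step count (41 h at 0.5 s/step).
    """

    mu: float = 3.0e-2
    k: float = 1.0e-3
    r_muscle: float = 6.0e-6
    r_hemocyte: float = 4.0e-6
    a_HF: float = 2.0e-9
    a_HH: float = 0.0
    a_FF: float = 0.0
    a_E: float = 1.0e-8
    v_hemocyte: float = 5.0e-9
    v_fat: float = 2.5e-9
    p_turn: float = 5.0e-3
    dt: float = 0.5
    field_size: float = 6.0e-4
    steps_total: int = 295_200
    time_origin: float = HAPF_ORIGIN

    def __post_init__(self) -> None:
        for name in ("mu", "k", "r_muscle", "r_hemocyte", "a_HF", "a_HH",
                     "a_FF", "a_E", "v_hemocyte", "v_fat", "field_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0.0 <= self.p_turn <= 1.0:
            raise ValueError("p_turn must be in [0, 1]")
        if not (self.a_E > self.a_HF and self.a_E > self.a_HH
                and self.a_E > self.a_FF):
            raise ValueError("phagocytosis adhesion a_E must exceed all "
                             "intercellular adhesion strengths")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class MotilityProfile:
    """Self-propulsion strength v [N] and per-step turning probability."""

    v: float
    p_turn: float
    label: str = "standard"

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if not 0.0 <= self.p_turn <= 1.0:
            raise ValueError("p_turn must be in [0, 1]")


#: subtype codes recorded per particle (index into SUBTYPE_LABELS)
SUBTYPE_LABELS = ("muscle", "standard", "slow", "fast", "meander",
                  "straight", "fat")
SUBTYPE_CODE = {lab: i for i, lab in enumerate(SUBTYPE_LABELS)}


@dataclass
class ParticleState:
    """Snapshot of one particle (positions in metres)."""

    id: int
    kind: Kind
    position: np.ndarray
    heading: np.ndarray
    radius: float
    radius_max: float
    profile: MotilityProfile
    muscle_state: MuscleState | None = None
    host_id: int | None = None
    float_started: bool = False


class World:
    """Full simulation state, stored as structure-of-arrays.

    ``positions``/``headings`` are (N, 2) float64 in metres; ``radius`` and
    ``radius_max`` (N,); ``kind`` the :class:`Kind` code; ``state`` the
    muscle state (−1 for non-muscle); ``host`` the host hemocyte index
    (−1 when none); ``v_base`` and ``p_turn`` the per-particle motility
    parameters.  Time-varying effective parameters (``mu_eff``, hemocyte
    propulsion multiplier, adhesion strengths, wall thickness) are plain
    attributes that schedule drivers may set between calls to
    :meth:`advance`.
    """

    def __init__(self, params: ModelParams, positions, headings, radius,
                 radius_max, kind, state, host, v_base, p_turn,
                 subtype=None, rng=None, fat_floating: bool = False):
        n = len(positions)
        self.params = params
        self.positions = np.ascontiguousarray(positions, dtype=np.float64)
        self.headings = np.ascontiguousarray(headings, dtype=np.float64)
        self.radius = np.asarray(radius, dtype=np.float64).copy()
        self.radius_max = np.asarray(radius_max, dtype=np.float64).copy()
        self.kind = np.asarray(kind, dtype=np.int8).copy()
        self.state = np.asarray(state, dtype=np.int8).copy()
        self.host = np.asarray(host, dtype=np.int32).copy()
        self.v_base = np.asarray(v_base, dtype=np.float64).copy()
        self.p_turn = np.asarray(p_turn, dtype=np.float64).copy()
        if subtype is None:
            subtype = np.where(self.kind == Kind.MUSCLE,
                               SUBTYPE_CODE["muscle"],
                               np.where(self.kind == Kind.FAT,
                                        SUBTYPE_CODE["fat"],
                                        SUBTYPE_CODE["standard"]))
        self.subtype = np.asarray(subtype, dtype=np.int8).copy()
        self.float_started = np.zeros(n, dtype=bool)
        self.float_started[(self.kind == Kind.FAT) & (self.radius > 0)] = True
        self.fat_floating = fat_floating
        self.rng = rng if rng is not None else np.random.default_rng()
        self.step_count = 0
        # schedule-controlled effective parameters
        self.mu_eff = params.mu
        self.v_mult = 1.0
        self.a_HF_eff = params.a_HF
        self.a_HH_eff = params.a_HH
        self.wall_w = 0.0
        self.walled = False
        self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_particles(cls, particles: list[ParticleState],
                       params: ModelParams, rng=None,
                       fat_floating: bool = False) -> "World":
        n = len(particles)
        pos = np.array([p.position for p in particles], float).reshape(n, 2)
        head = np.array([p.heading for p in particles], float).reshape(n, 2)
        rad = np.array([p.radius for p in particles], float)
        radm = np.array([p.radius_max for p in particles], float)
        kind = np.array([int(p.kind) for p in particles])
        state = np.array([int(p.muscle_state) if p.muscle_state is not None
                          else -1 for p in particles])
        host = np.array([p.host_id if p.host_id is not None else -1
                         for p in particles])
        v = np.array([p.profile.v for p in particles], float)
        pt = np.array([p.profile.p_turn for p in particles], float)
        sub = np.array([SUBTYPE_CODE.get(p.profile.label,
                                         SUBTYPE_CODE["standard"])
                        for p in particles])
        return cls(params, pos, head, rad, radm, kind, state, host, v, pt,
                   subtype=sub, rng=rng, fat_floating=fat_floating)

    def _validate(self) -> None:
        L = self.params.field_size
        if np.any(self.positions < 0) or np.any(self.positions >= L):
            self.positions %= L
        if np.any(self.radius > self.radius_max + 1e-12):
            raise ValueError("radius exceeds radius_max")
        norms = np.linalg.norm(self.headings, axis=1)
        bad = np.abs(norms - 1.0) > 1e-9
        if np.any(bad & (self.v_base > 0)):
            raise ValueError("headings must be unit vectors")
        eaten = np.flatnonzero((self.kind == Kind.MUSCLE)
                               & (self.state == int(MuscleState.EATEN)))
        for i in eaten:
            h = self.host[i]
            if h < 0 or self.kind[h] != Kind.HEMOCYTE:
                raise ValueError(f"eaten muscle {i} has invalid host {h}")
        if np.any(self.v_base[self.kind == Kind.MUSCLE] != 0):
            raise ValueError("muscle units cannot self-propel")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def hapf(self) -> float:
        return step_to_hapf(self.step_count)

    def particle(self, i: int) -> ParticleState:
        if not 0 <= i < self.n:
            raise KeyError(f"unknown particle id {i}")
        kind = Kind(int(self.kind[i]))
        labels = {0: "muscle", 2: "fat"}
        label = SUBTYPE_LABELS[self.subtype[i]]
        prof = MotilityProfile(float(self.v_base[i]), float(self.p_turn[i]),
                               labels.get(int(kind), label))
        ms = (MuscleState(int(self.state[i]))
              if kind == Kind.MUSCLE else None)
        host = int(self.host[i]) if self.host[i] >= 0 else None
        return ParticleState(i, kind, self.positions[i].copy(),
                             self.headings[i].copy(), float(self.radius[i]),
                             float(self.radius_max[i]), prof, ms, host,
                             bool(self.float_started[i]))

    # -- effective per-particle propulsion ------------------------------------

    def v_effective(self) -> np.ndarray:
        v = self.v_base.copy()
        hem = self.kind == Kind.HEMOCYTE
        v[hem] *= self.v_mult
        v[(self.kind == Kind.FAT) & (self.radius <= 0)] = 0.0
        return v

    # -- dynamics -------------------------------------------------------------

    def advance(self, n_steps: int) -> "World":
        """Run ``n_steps`` synchronous Euler steps with the current effective
        parameters (no schedule evaluation or fat-radius ramping; drivers in
        :mod:`histolysim.scenarios` call those at minute boundaries)."""
        if n_steps <= 0:
            return self
        p = self.params
        turn_u = self.rng.random((n_steps, self.n))
        turn_ang = self.rng.uniform(0.0, 2.0 * math.pi, (n_steps, self.n))
        small = self.kind != Kind.FAT
        r_small = 2.0 * (self.radius[small].max() if small.any() else p.r_muscle)
        code, pi, si = _kernels.run_chunk(
            self.positions, self.headings, self.radius, self.kind,
            self.state, self.host, self.v_effective(), self.p_turn,
            self.mu_eff, p.k, self.a_HF_eff, self.a_HH_eff, p.a_FF, p.a_E,
            p.dt, p.field_size, self.wall_w, self.walled, r_small,
            turn_u, turn_ang)
        if code != 0:
            raise SimulationBlowupError(
                f"non-finite position for particle {pi} at step "
                f"{self.step_count + si}")
        self.step_count += n_steps
        return self

    def update_fat_radii(self) -> "World":
        """Minute-cadence fat-body radius ramp (floating scenarios).

        From step 14,400 a not-yet-floating fat body cell starts its ramp at
        the first minute boundary at which no uneaten muscle-unit disk
        overlaps its full-radius disk; thereafter the radius grows by
        0.383 um per minute up to the cell's maximum.  Propulsion is enabled
        while the radius is positive.
        """
        if not self.fat_floating or self.step_count < FAT_FLOAT_START_STEP:
            return self
        fat = np.flatnonzero(self.kind == Kind.FAT)
        if fat.size == 0:
            return self
        pend = fat[~self.float_started[fat]]
        if pend.size:
            mus = ((self.kind == Kind.MUSCLE)
                   & (self.state == int(MuscleState.UNEATEN)))
            mpos = self.positions[mus]
            L = self.params.field_size
            for f in pend:
                if mpos.size:
                    d = mpos - self.positions[f]
                    d -= L * np.round(d / L)
                    lim = self.radius_max[f] + self.params.r_muscle
                    if np.any(np.einsum("ij,ij->i", d, d) < lim * lim):
                        continue
                self.float_started[f] = True
        grow = fat[self.float_started[fat]]
        self.radius[grow] = np.minimum(self.radius[grow] + FAT_RADIUS_INCREMENT,
                                       self.radius_max[grow])
        return self


# -- single-pair / single-particle reference operations ------------------------
# These are the readable NumPy counterparts of the compiled kernel; the test
# suite checks that one kernel step equals their composition.


def _min_image(d: np.ndarray, L: float, periodic_y: bool = True) -> np.ndarray:
    d = np.asarray(d, float).copy()
    d[..., 0] -= L * np.round(d[..., 0] / L)
    if periodic_y:
        d[..., 1] -= L * np.round(d[..., 1] / L)
    return d


def contact_set(world: World, i: int, params: ModelParams | None = None) -> set[int]:
    """Indices of particles in strict overlap with particle ``i``.

    Overlap means minimum-image center distance strictly below the sum of
    radii; tangency does not count.  Radius-zero particles (fat body cells
    still in the depth) interact with nothing.
    """
    p = params or world.params
    if not 0 <= i < world.n:
        raise KeyError(f"unknown particle id {i}")
    if world.radius[i] <= 0:
        return set()
    d = _min_image(world.positions - world.positions[i], p.field_size,
                   periodic_y=not world.walled)
    dist = np.hypot(d[:, 0], d[:, 1])
    rsum = world.radius + world.radius[i]
    hit = (dist < rsum) & (world.radius > 0)
    hit[i] = False
    return set(np.flatnonzero(hit).tolist())


def adhesion_coefficient(pi: ParticleState, pj: ParticleState,
                         params: ModelParams) -> float:
    """Adhesion strength [N] acting between two contacting particles.

    An uneaten muscle unit adheres to any hemocyte with the phagocytosis
    strength ``a_E``; an eaten muscle unit keeps ``a_E`` with its own host
    only.  For the intercellular strengths, an eaten muscle unit counts as a
    hemocyte (it is enclosed in its host's cytoplasm); an uneaten one
    adheres to nothing else.
    """
    if pi.id == pj.id:
        raise ValueError("adhesion_coefficient requires distinct particles")

    def eff_kind(p: ParticleState) -> int:
        if p.kind == Kind.MUSCLE and p.muscle_state == MuscleState.EATEN:
            return int(Kind.HEMOCYTE)
        return int(p.kind)

    for a, b in ((pi, pj), (pj, pi)):
        if a.kind == Kind.MUSCLE and b.kind == Kind.HEMOCYTE:
            if a.muscle_state == MuscleState.UNEATEN:
                return params.a_E
            if a.host_id == b.id:
                return params.a_E
    ki, kj = eff_kind(pi), eff_kind(pj)
    if Kind.MUSCLE in (ki, kj):
        return 0.0
    if ki == kj == Kind.HEMOCYTE:
        return params.a_HH
    if ki == kj == Kind.FAT:
        return params.a_FF
    return params.a_HF


def pairwise_force(pi: ParticleState, pj: ParticleState, params: ModelParams,
                   a_HF: float | None = None, a_HH: float | None = None,
                   periodic_y: bool = True) -> np.ndarray:
    """Contact force [N] on particle ``i`` from particle ``j``.

    Linear repulsion on the overlap length plus the pair's adhesion, along
    the minimum-image center line; antisymmetric between the pair.  At
    coincident centers the direction is +x for the lower id (and adhesion is
    dropped for a host-carried pair, which is legitimately concentric and at
    rest there).
    """
    p = params
    if a_HF is not None or a_HH is not None:
        p = params.with_(a_HF=params.a_HF if a_HF is None else a_HF,
                         a_HH=params.a_HH if a_HH is None else a_HH)
    d = _min_image(pj.position - pi.position, p.field_size, periodic_y)
    dist = float(np.hypot(d[0], d[1]))
    rsum = pi.radius + pj.radius
    if dist >= rsum:
        return np.zeros(2)
    if dist == 0.0:
        host_pair = ((pi.kind == Kind.MUSCLE and pi.host_id == pj.id)
                     or (pj.kind == Kind.MUSCLE and pj.host_id == pi.id))
        if host_pair:
            return np.zeros(2)
        e = np.array([1.0, 0.0]) if pi.id < pj.id else np.array([-1.0, 0.0])
        return -p.k * rsum * e
    a_ij = adhesion_coefficient(pi, pj, p)
    e = d / dist
    return (-p.k * (rsum - dist) + a_ij) * e


def wall_force(p: ParticleState, w: float, params: ModelParams,
               field_size: float | None = None) -> np.ndarray:
    """Repulsion [N] from the confining top/bottom slabs of thickness ``w``."""
    if w <= 0:
        return np.zeros(2)
    L = field_size if field_size is not None else params.field_size
    y = float(p.position[1])
    d_bot, d_top = y, L - y
    y_p = min(d_bot, d_top)
    overlap = p.radius + w - y_p
    if overlap <= 0:
        return np.zeros(2)
    away = 1.0 if d_bot <= d_top else -1.0
    return np.array([0.0, params.k * overlap * away])


def turning_update(p: ParticleState, rng) -> ParticleState:
    """Redraw the heading uniformly with the particle's turning probability.

    No-op for non-motile particles (muscle units, submerged fat cells)."""
    if p.profile.v <= 0:
        return p
    if rng.random() < p.profile.p_turn:
        ang = rng.uniform(0.0, 2.0 * math.pi)
        p = replace(p, heading=np.array([math.cos(ang), math.sin(ang)]))
    return p


def phagocytosis_update(world: World) -> World:
    """Flip uneaten muscle units overlapping a hemocyte to the eaten state.

    The host is the overlapping hemocyte with the nearest center (ties to
    the lowest index).  Already-eaten units never change host here; a
    hemocyte may host any number of units.
    """
    L = world.params.field_size
    uneaten = np.flatnonzero((world.kind == Kind.MUSCLE)
                             & (world.state == int(MuscleState.UNEATEN)))
    hem = np.flatnonzero(world.kind == Kind.HEMOCYTE)
    if hem.size == 0:
        return world
    for i in uneaten:
        d = _min_image(world.positions[hem] - world.positions[i], L,
                       periodic_y=not world.walled)
        dist = np.hypot(d[:, 0], d[:, 1])
        rsum = world.radius[i] + world.radius[hem]
        ov = dist < rsum
        if np.any(ov):
            cand = hem[ov]
            dc = dist[ov]
            best = cand[np.lexsort((cand, dc))[0]]
            world.state[i] = int(MuscleState.EATEN)
            world.host[i] = best
    return world


def bond_break_update(world: World) -> World:
    """Release eaten muscle units that lost contact with their host."""
    L = world.params.field_size
    eaten = np.flatnonzero((world.kind == Kind.MUSCLE)
                           & (world.state == int(MuscleState.EATEN)))
    for i in eaten:
        h = world.host[i]
        if h < 0 or world.kind[h] != Kind.HEMOCYTE:
            raise RuntimeError(f"eaten muscle {i} has invalid host {h}")
        d = _min_image(world.positions[h] - world.positions[i], L,
                       periodic_y=not world.walled)
        if np.hypot(d[0], d[1]) >= world.radius[i] + world.radius[h]:
            world.state[i] = int(MuscleState.UNEATEN)
            world.host[i] = -1
    return world


def fat_radius_update(world: World, i: int) -> ParticleState:
    """Spec surface for the per-cell radius ramp; see
    :meth:`World.update_fat_radii` for the batch driver."""
    world.update_fat_radii()
    return world.particle(i)


def step(world: World, n_steps: int = 1) -> World:
    """Advance the world by ``n_steps`` full update cycles."""
    return world.advance(n_steps)
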