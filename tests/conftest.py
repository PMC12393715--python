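import numpy as np
import pytest

from histolysim.mechanics import (Kind, ModelParams, MotilityProfile,
                                  MuscleState, ParticleState, World)

UM = 1e-6


def make_particle(pid, kind, x_um, y_um, *, radius=None, v=0.0, p_turn=0.0,
                  heading=(1.0, 0.0), state=None, host=None, radius_max=None,
                  label="standard"):
    p = ModelParams()
    if radius is None:
        radius = {Kind.MUSCLE: p.r_muscle, Kind.HEMOCYTE: p.r_hemocyte,
                  Kind.FAT: 23e-6}[kind]
    if state is None and kind == Kind.MUSCLE:
        state = MuscleState.UNEATEN
    return ParticleState(
        id=pid, kind=kind, position=np.array([x_um, y_um]) * UM,
        heading=np.asarray(heading, float), radius=radius,
        radius_max=radius if radius_max is None else radius_max,
        profile=MotilityProfile(v, p_turn, label),
        muscle_state=state, host_id=host)


def make_world(particles, *, params=None, seed=0, fat_floating=False):
    return World.from_particles(particles, params or ModelParams(),
                                rng=np.random.default_rng(seed),
                                fat_floating=fat_floating)


@pytest.fixture
def pair_world():
    """A hemocyte and an uneaten muscle unit 9 um apart, far from others."""
    return make_world([
        make_particle(0, Kind.MUSCLE, 300.0, 300.0),
        make_particle(1, Kind.HEMOCYTE, 309.0, 300.0, v=5e-9, p_turn=0.005),
    ])
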