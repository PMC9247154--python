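"""Shared fixtures: phantoms generated once per session at fixed seeds."""
from __future__ import annotations

import numpy as np
import pytest

import bonetomo as bt
from bonetomo.phantom import Cylinder, Everywhere, Phase, PhantomSpec, PLUG_NOISE_SD


@pytest.fixture(scope="session")
def three_phase_result():
    """Nested-cylinder plug: chunky void/bone/marrow regions, well separated.

    The central void cylinder is capped in z so that it is interior (a dark
    channel open to the volume face would legitimately count as exterior).
    """
    phases = (
        Phase("background", Everywhere(), 6000),
        Phase("marrow", Cylinder((48, 48), 40), 38000),
        Phase("bone", Cylinder((48, 48), 28), 22000),
        Phase("void", Cylinder((48, 48), 14, z_range=(8, 56)), 9000),
    )
    spec = PhantomSpec(
        shape=(64, 96, 96), phases=phases, noise_sigma=PLUG_NOISE_SD, seed=9
    )
    return bt.generate_volume(spec)


@pytest.fixture(scope="session")
def three_phase_means():
    return {"void": 9000.0, "bone": 22000.0, "marrow": 38000.0}


@pytest.fixture(scope="session")
def soaked_result():
    return bt.generate_volume(bt.plug_phantom(state="soaked", seed=2))


@pytest.fixture(scope="session")
def dry_result():
    return bt.generate_volume(bt.plug_phantom(state="dry", seed=3))


@pytest.fixture(scope="session")
def tibia_results():
    return {
        state: bt.generate_volume(bt.tibia_phantom(state=state, seed=4))
        for state in ("dry", "rehydrated_12h", "rehydrated_40h")
    }


@pytest.fixture(scope="session")
def halfvol():
    """Noise-free, blur-free two-phase half volume at greys 1000/3000."""
    from bonetomo.phantom import HalfSpace

    spec = PhantomSpec(
        shape=(8, 32, 32),
        phases=(
            Phase("low", Everywhere(), 1000),
            Phase("high", HalfSpace(axis=2, cut=16), 3000),
        ),
        blur_sigma=0.0,
        noise_sigma=0.0,
        seed=0,
    )
    return bt.generate_volume(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
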