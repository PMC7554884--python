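from __future__ import annotations

import math

import numpy as np
import pytest

from waternet.fixtures import (
    RIGID_HOH_ANGLE_DEG,
    RIGID_OH_LENGTH,
    PlantSpec,
    generate_frames,
)
from waternet.structures_io import Atom, Frame, WaterMolecule


def make_water(index: int, o_pos, h1_dir, h2_dir, residue_id=None) -> WaterMolecule:
    """Water with O at o_pos and hydrogens along the given unit directions."""
    o_pos = np.asarray(o_pos, dtype=float)
    h1_dir = np.asarray(h1_dir, dtype=float)
    h2_dir = np.asarray(h2_dir, dtype=float)
    resid = residue_id if residue_id is not None else index + 1

    def atom(element, name, pos):
        return Atom(element=element, name=name, position=pos,
                    residue_name="HOH", residue_id=resid)

    return WaterMolecule(
        index=index,
        oxygen=atom("O", "O", o_pos),
        hydrogen1=atom("H", "H1", o_pos + RIGID_OH_LENGTH * h1_dir / np.linalg.norm(h1_dir)),
        hydrogen2=atom("H", "H2", o_pos + RIGID_OH_LENGTH * h2_dir / np.linalg.norm(h2_dir)),
    )


def random_water(index: int, rng: np.random.Generator, span: float = 10.0) -> WaterMolecule:
    """Randomly placed and oriented rigid water."""
    from waternet._util import random_rotation

    theta = math.radians(RIGID_HOH_ANGLE_DEG)
    half = theta / 2.0
    rot = random_rotation(rng)
    d1 = rot @ np.array([math.sin(half), 0.0, math.cos(half)])
    d2 = rot @ np.array([-math.sin(half), 0.0, math.cos(half)])
    return make_water(index, rng.uniform(0, span, 3), d1, d2)


def ideal_hbond_dimer() -> tuple[WaterMolecule, WaterMolecule]:
    """Donor O-H aimed at the acceptor O at 2.75 Å, acceptor H's pointing away."""
    theta = math.radians(RIGID_HOH_ANGLE_DEG)
    half = theta / 2.0
    donor = make_water(
        0, [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [math.cos(theta), math.sin(theta), 0.0],
    )
    acceptor = make_water(
        1, [2.75, 0.0, 0.0],
        [math.cos(half), 0.0, math.sin(half)],
        [math.cos(half), 0.0, -math.sin(half)],
    )
    return donor, acceptor


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def planted_spec() -> PlantSpec:
    """2 x R3 + 1 x R6 per frame, 10 frames, no jitter."""
    return PlantSpec(
        rings_to_plant=(
            ("R3", (8.0, 8.0, 8.0), 1),
            ("R3", (8.0, 22.0, 8.0), 2),
            ("R6", (22.0, 15.0, 20.0), 3),
        ),
        n_noise_waters=12,
        box=(30.0, 30.0, 30.0),
        n_frames=10,
        jitter_sigma=0.0,
        random_seed=42,
    )


@pytest.fixture
def planted_frames(planted_spec) -> list[Frame]:
    return generate_frames(planted_spec)
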