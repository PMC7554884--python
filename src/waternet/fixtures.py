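"""Synthetic test inputs: water boxes with planted rings, toy ligands, sites.

Everything here is deterministic given its seed and carries no physical
realism beyond what the analysis pipeline needs: planted rings are regular
polygons of rigid 3-site waters whose consecutive pairs provably satisfy the
H-bond energy criterion (asserted at generation time), noise waters are
randomly oriented and rejected on close contact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._util import random_rotation
from .structures_io import Atom, Frame, TIP3PParams, WaterMolecule, write_pdb
from .site_regions import Region, RegionSpec
from .water_networks import pair_energy

__all__ = [
    "PlantSpec",
    "GenerationError",
    "CapacityError",
    "RIGID_OH_LENGTH",
    "RIGID_HOH_ANGLE_DEG",
    "plant_ring",
    "generate_frames",
    "write_frames",
    "make_toy_ligand",
    "region_spec_for_plants",
    "write_truth",
]

#: Rigid 3-site internal geometry used for all generated waters.
RIGID_OH_LENGTH = 0.9572
RIGID_HOH_ANGLE_DEG = 104.52

#: Canonical O-O spacing (Å) for planted rings: a textbook H-bond distance.
PLANT_OO_SPACING = 2.75

#: Minimum O-O separation (Å) enforced between noise waters and anything else.
NOISE_CLASH_DISTANCE = 2.5

_RING_SIZES = {"R3": 3, "R4": 4, "R5": 5, "R6": 6}

# In-plane tilt (degrees) of the donor O-H off the O-O edge, per ring size.
# The small-ring geometry is strained; tilting the donor slightly outward
# deepens the pair energy (R3: -3.4 -> -5.8 kcal/mol), giving planted rings
# a wide margin below the H-bond criterion so they survive jitter.
_DONOR_TILT_DEG = {3: -15.0, 4: -5.0, 5: 0.0, 6: 5.0}


class GenerationError(RuntimeError):
    """Planted geometry failed its own H-bond criterion check."""


class CapacityError(RuntimeError):
    """Could not place the requested noise waters without clashes."""


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for a synthetic multi-frame water box.

    ``rings_to_plant`` is a list of (ring_class, center, orientation_seed)
    tuples; each planted ring keeps its orientation across frames while
    per-frame jitter (rigid per-water Gaussian translation, ``jitter_sigma``)
    and noise waters are redrawn from the single ``random_seed`` stream.
    """

    rings_to_plant: tuple = ()
    n_noise_waters: int = 0
    box: tuple[float, float, float] = (30.0, 30.0, 30.0)
    n_frames: int = 1
    jitter_sigma: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_noise_waters < 0:
            raise ValueError("n_noise_waters must be >= 0")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for (ring_class, _center, _seed) in self.rings_to_plant:
            if ring_class not in _RING_SIZES:
                raise ValueError(f"unknown ring class {ring_class!r}")


def _water_from_local(
    index: int,
    o_pos: np.ndarray,
    h1_pos: np.ndarray,
    h2_pos: np.ndarray,
    residue_id: int,
) -> WaterMolecule:
    def atom(element: str, name: str, pos: np.ndarray) -> Atom:
        return Atom(
            element=element,
            name=name,
            position=np.asarray(pos, dtype=float),
            residue_name="HOH",
            residue_id=residue_id,
        )

    return WaterMolecule(
        index=index,
        oxygen=atom("O", "O", o_pos),
        hydrogen1=atom("H", "H1", h1_pos),
        hydrogen2=atom("H", "H2", h2_pos),
    )


def plant_ring(
    ring_class: str,
    center,
    orientation_seed: int = 0,
    spacing: float = PLANT_OO_SPACING,
    params: TIP3PParams = TIP3PParams(),
) -> list[WaterMolecule]:
    """Regular n-gon of waters whose consecutive pairs are hydrogen-bonded.

    Oxygens sit on a circle with O-O spacing ``spacing``; each water donates
    its first hydrogen along the edge to the next oxygen, with the second
    hydrogen kept in the ring plane pointing away from the cycle (this
    orientation keeps even the strained R3 pairs below the energy
    criterion). The whole ring is rotated by a
    seeded random rotation and translated to ``center``. Consecutive pair
    energies are checked against the criterion and a failure raises
    :class:`GenerationError` (it would indicate a geometry/parameter bug).
    """
    if ring_class not in _RING_SIZES:
        raise ValueError(f"unknown ring class {ring_class!r}; expected R3..R6")
    n = _RING_SIZES[ring_class]
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(orientation_seed)
    rot = random_rotation(rng)

    circumradius = spacing / (2.0 * math.sin(math.pi / n))
    angles = 2.0 * math.pi * np.arange(n) / n
    oxygens = np.stack(
        [circumradius * np.cos(angles), circumradius * np.sin(angles), np.zeros(n)],
        axis=1,
    )
    theta = math.radians(RIGID_HOH_ANGLE_DEG)
    tilt = math.radians(_DONOR_TILT_DEG[n])
    z = np.array([0.0, 0.0, 1.0])
    waters = []
    for i in range(n):
        o = oxygens[i]
        u = oxygens[(i + 1) % n] - o
        u = u / np.linalg.norm(u)
        # donor direction: along the edge, tilted slightly within the plane
        donor = math.cos(tilt) * u + math.sin(tilt) * np.cross(z, u)
        outward = np.cross(donor, z)  # in-plane, away from the ring interior
        h1 = o + RIGID_OH_LENGTH * donor
        h2 = o + RIGID_OH_LENGTH * (
            math.cos(theta) * donor + math.sin(theta) * outward
        )
        waters.append(
            _water_from_local(
                index=i,
                o_pos=rot @ o + center,
                h1_pos=rot @ h1 + center,
                h2_pos=rot @ h2 + center,
                residue_id=i + 1,
            )
        )
    for i in range(n):
        e = pair_energy(waters[i], waters[(i + 1) % n], params)
        if e > params.hbond_energy_criterion:
            raise GenerationError(
                f"planted {ring_class} pair ({i}, {(i + 1) % n}) has energy "
                f"{e:.3f} kcal/mol above criterion {params.hbond_energy_criterion}"
            )
    return waters


def _random_water(
    index: int, o_pos: np.ndarray, rng: np.random.Generator, residue_id: int
) -> WaterMolecule:
    theta = math.radians(RIGID_HOH_ANGLE_DEG)
    half = theta / 2.0
    local_h1 = RIGID_OH_LENGTH * np.array([math.sin(half), 0.0, math.cos(half)])
    local_h2 = RIGID_OH_LENGTH * np.array([-math.sin(half), 0.0, math.cos(half)])
    rot = random_rotation(rng)
    return _water_from_local(
        index=index,
        o_pos=o_pos,
        h1_pos=o_pos + rot @ local_h1,
        h2_pos=o_pos + rot @ local_h2,
        residue_id=residue_id,
    )


def generate_frames(
    spec: PlantSpec, params: TIP3PParams = TIP3PParams()
) -> list[Frame]:
    """Materialize the synthetic frames described by ``spec``.

    Planted ring waters are jittered per frame by rigid per-water Gaussian
    translations; noise waters are uniform in the box with random
    orientations, rejected within :data:`NOISE_CLASH_DISTANCE` of any
    existing oxygen (up to 10^4 attempts each, then :class:`CapacityError`).
    """
    rng = np.random.default_rng(spec.random_seed)
    box = np.asarray(spec.box, dtype=float)
    base_rings = [
        plant_ring(ring_class, c, orientation_seed=oseed, params=params)
        for (ring_class, c, oseed) in spec.rings_to_plant
    ]
    frames: list[Frame] = []
    for frame_idx in range(spec.n_frames):
        waters: list[WaterMolecule] = []
        occupied: list[np.ndarray] = []
        index = 0
        for ring_waters in base_rings:
            for w in ring_waters:
                shift = rng.normal(0.0, spec.jitter_sigma, size=3) \
                    if spec.jitter_sigma > 0 else np.zeros(3)
                pos = w.positions + shift
                waters.append(
                    _water_from_local(index, pos[0], pos[1], pos[2], index + 1)
                )
                occupied.append(pos[0])
                index += 1
        for _ in range(spec.n_noise_waters):
            for _attempt in range(10_000):
                o_pos = rng.uniform(0.0, 1.0, size=3) * box
                if occupied:
                    dmin = min(
                        float(np.linalg.norm(o_pos - q)) for q in occupied
                    )
                    if dmin < NOISE_CLASH_DISTANCE:
                        continue
                break
            else:
                raise CapacityError(
                    f"frame {frame_idx + 1}: could not place noise water "
                    f"{len(waters) + 1} in box {tuple(box)} after 10000 attempts"
                )
            waters.append(_random_water(index, o_pos, rng, index + 1))
            occupied.append(o_pos)
            index += 1
        frames.append(Frame(waters=waters, box=box.copy(), frame_id=frame_idx + 1))
    return frames


def write_frames(frames: Sequence[Frame], path) -> None:
    """Write generated frames as a multi-MODEL PDB (round-trips with the parser)."""
    write_pdb(frames, path)


def make_toy_ligand(shape: str, n_atoms: int, seed: int = 0) -> list[Atom]:
    """Deterministic heavy-atom point cloud: 'rod', 'ring' or 'blob'.

    Elements cycle through C/N/O; coordinates are reproducible from the seed.
    """
    if n_atoms < 4:
        raise ValueError(f"toy ligand needs >= 4 atoms, got {n_atoms}")
    rng = np.random.default_rng(seed)
    if shape == "rod":
        t = np.linspace(0.0, 1.5 * (n_atoms - 1), n_atoms)
        pts = np.stack([t, np.zeros(n_atoms), np.zeros(n_atoms)], axis=1)
        pts += rng.normal(0.0, 0.1, size=pts.shape)
    elif shape == "ring":
        ang = 2.0 * math.pi * np.arange(n_atoms) / n_atoms
        radius = 1.4 / (2.0 * math.sin(math.pi / n_atoms)) * 2.0
        pts = np.stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_atoms)], axis=1
        )
        pts += rng.normal(0.0, 0.05, size=pts.shape)
    elif shape == "blob":
        pts = rng.normal(0.0, 1.5, size=(n_atoms, 3))
    else:
        raise ValueError(f"unknown toy-ligand shape {shape!r}")
    elements = ["C", "N", "O"]
    return [
        Atom(
            element=elements[i % 3],
            name=f"{elements[i % 3]}{i + 1}",
            position=pts[i],
            residue_name="LIG",
            residue_id=1,
        )
        for i in range(n_atoms)
    ]


def region_spec_for_plants(
    spec: PlantSpec, radius: float = 4.0, names: Optional[Sequence[str]] = None
) -> RegionSpec:
    """One spherical region around each planted ring center (A, B, C, ...)."""
    if not spec.rings_to_plant:
        raise ValueError("no planted rings to build regions from")
    if names is None:
        names = [chr(ord("A") + i) for i in range(len(spec.rings_to_plant))]
    regions = [
        Region(name=name, center=np.asarray(c, dtype=float), radius=radius)
        for name, (_cls, c, _seed) in zip(names, spec.rings_to_plant)
    ]
    return RegionSpec(regions)


def write_truth(spec: PlantSpec, path) -> None:
    """JSON record of what was planted, for test assertions."""
    payload = {
        "n_frames": spec.n_frames,
        "n_noise_waters": spec.n_noise_waters,
        "jitter_sigma": spec.jitter_sigma,
        "random_seed": spec.random_seed,
        "box": list(spec.box),
        "rings": [
            {
                "ring_class": ring_class,
                "center": [float(x) for x in np.asarray(center, dtype=float)],
                "orientation_seed": oseed,
            }
            for (ring_class, center, oseed) in spec.rings_to_plant
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
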