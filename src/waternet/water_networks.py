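"""Hydrogen-bond graph construction and water-ring (R3-R6) enumeration.

The pair interaction of two rigid 3-site waters is the 9-term Coulomb sum
over their charge sites plus a single oxygen-oxygen Lennard-Jones term. A
pair is hydrogen-bonded when that energy falls at or below the configured
criterion (default -2.25 kcal/mol). Rings are the chordless simple cycles of
the resulting graph, sizes 3 through 6, reported once each in canonical
order with their (all-atom, mass-weighted) centers of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures_io import Frame, TIP3PParams, WaterMolecule

__all__ = [
    "HBondGraph",
    "WaterRing",
    "SingularGeometryError",
    "FrameAnalysisError",
    "DEFAULT_OO_CUTOFF",
    "pair_energy",
    "build_hbond_graph",
    "enumerate_rings",
    "ring_center_of_mass",
    "analyze_frames",
    "write_ring_table",
    "write_ring_com_pdb",
]

#: O-O distance prefilter in Å: no rigid 3-site pair beyond this reaches the
#: default H-bond criterion, so farther pairs are skipped before the energy
#: evaluation. Exposed for auditing.
DEFAULT_OO_CUTOFF = 3.5


class SingularGeometryError(ValueError):
    """Two interaction sites coincide; the pair energy is undefined."""


class FrameAnalysisError(RuntimeError):
    """Analysis of one frame failed; message carries the frame_id."""


@dataclass
class HBondGraph:
    """Undirected H-bond graph over water indices.

    ``edges`` maps sorted index pairs to the pair energy (kcal/mol); every
    stored energy satisfies the criterion used at construction.
    """

    nodes: list[int]
    edges: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-edge on water {a}")
            if a > b:
                raise ValueError(f"edge ({a}, {b}) not in sorted order")

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {n: set() for n in self.nodes}
        for (a, b) in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class WaterRing:
    """A chordless cycle of 3-6 waters, in canonical member order."""

    members: tuple[int, ...]
    frame_id: int = 1
    center_of_mass: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.members = tuple(int(m) for m in self.members)
        if not 3 <= len(self.members) <= 6:
            raise ValueError(f"ring size {len(self.members)} outside 3..6")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"ring members not distinct: {self.members}")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def ring_class(self) -> str:
        return f"R{len(self.members)}"


def _site_positions(w: WaterMolecule) -> np.ndarray:
    return w.positions


def pair_energy(
    a: WaterMolecule,
    b: WaterMolecule,
    params: TIP3PParams = TIP3PParams(),
    shift_b: Optional[np.ndarray] = None,
) -> float:
    """Interaction energy (kcal/mol) of two rigid 3-site waters.

    Nine Coulomb site-site terms plus the O-O Lennard-Jones term. ``shift_b``
    rigidly translates molecule ``b`` before evaluation (used for the
    minimum-image convention).
    """
    if a is b:
        raise ValueError("pair_energy requires two distinct waters")
    pa = _site_positions(a)
    pb = _site_positions(b)
    if shift_b is not None:
        pb = pb + shift_b
    q = np.asarray(params.charges)
    diff = pa[:, None, :] - pb[None, :, :]
    r = np.sqrt((diff * diff).sum(axis=2))
    if np.any(r <= 0.0):
        raise SingularGeometryError(
            f"coincident interaction sites between waters {a.index} and {b.index}"
        )
    coulomb = params.coulomb_constant * float((q[:, None] * q[None, :] / r).sum())
    r_oo = float(r[0, 0])
    lj = params.A / r_oo**12 - params.C / r_oo**6
    return coulomb + lj


def build_hbond_graph(
    frame: Frame,
    params: TIP3PParams = TIP3PParams(),
    cutoff: float = DEFAULT_OO_CUTOFF,
    minimum_image: bool = False,
) -> HBondGraph:
    """H-bond graph of a frame: edge iff O-O <= cutoff and energy <= criterion."""
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if minimum_image and frame.box is None:
        raise ValueError("minimum_image requested but frame has no box")
    waters = frame.waters
    nodes = [w.index for w in waters]
    edges: dict[tuple[int, int], float] = {}
    if len(waters) < 2:
        return HBondGraph(nodes=nodes, edges=edges)

    opos = frame.oxygen_positions()
    if minimum_image:
        box = frame.box
        n = len(waters)
        for i in range(n - 1):
            delta = opos[i + 1 :] - opos[i]
            shift = -box * np.round(delta / box)
            dmin = np.linalg.norm(delta + shift, axis=1)
            for off in np.nonzero(dmin <= cutoff)[0]:
                j = i + 1 + int(off)
                e = pair_energy(waters[i], waters[j], params, shift_b=shift[off])
                if e <= params.hbond_energy_criterion:
                    key = tuple(sorted((waters[i].index, waters[j].index)))
                    edges[key] = e
    else:
        tree = cKDTree(opos)
        for i, j in sorted(tree.query_pairs(cutoff)):
            e = pair_energy(waters[i], waters[j], params)
            if e <= params.hbond_energy_criterion:
                key = tuple(sorted((waters[i].index, waters[j].index)))
                edges[key] = e
    return HBondGraph(nodes=nodes, edges=edges)


def enumerate_rings(
    graph: HBondGraph, min_size: int = 3, max_size: int = 6
) -> list[WaterRing]:
    """Every chordless simple cycle of size min_size..max_size, once each.

    Canonical form: the smallest member first, then the direction whose
    second member is smaller; results sorted by (size, members). Centers of
    mass are not filled in here.
    """
    if min_size < 3:
        raise ValueError(f"min_size must be >= 3, got {min_size}")
    if max_size > 6:
        raise ValueError(f"max_size must be <= 6, got {max_size}")
    adj = graph.adjacency()
    found: list[tuple[int, ...]] = []

    # DFS over paths (s, v1, ..) with all vi > s, so s is the cycle minimum
    # and each cycle is visited from a unique root. Chordlessness is enforced
    # incrementally: a new vertex may touch only the path tip, plus the root
    # when it closes the cycle (in which case the path cannot grow further).
    for s in sorted(adj):
        stack: list[tuple[int, ...]] = [(s,)]
        while stack:
            path = stack.pop()
            tip = path[-1]
            internal = path[1:-1]
            for v in sorted(adj[tip], reverse=True):
                if v <= s or v in path:
                    continue
                if any(v in adj[w] for w in internal):
                    continue  # would create a chord
                # for a 1-vertex path the s-v edge is the path edge itself,
                # not a closure
                closes = len(path) >= 2 and s in adj[v]
                if closes:
                    size = len(path) + 1
                    if min_size <= size <= max_size and path[1] < v:
                        found.append(path + (v,))
                    # any extension past v would leave the chord v-s behind
                elif len(path) + 1 < max_size:
                    stack.append(path + (v,))
    found.sort(key=lambda m: (len(m), m))
    return [WaterRing(members=m) for m in found]


def ring_center_of_mass(
    ring: WaterRing, frame: Frame, com_mode: str = "all"
) -> np.ndarray:
    """Mass-weighted mean position of the ring's member waters.

    ``com_mode='all'`` uses all 3 atoms per water; ``'oxygen'`` uses the
    unweighted oxygen centroid (sensitivity-check variant).
    """
    lookup = frame.water_by_index
    missing = [m for m in ring.members if m not in lookup]
    if missing:
        raise KeyError(
            f"frame {frame.frame_id}: ring members {missing} not present"
        )
    if com_mode == "oxygen":
        pts = np.stack([lookup[m].oxygen.position for m in ring.members])
        return pts.mean(axis=0)
    if com_mode != "all":
        raise ValueError(f"unknown com_mode {com_mode!r}")
    positions = []
    masses = []
    for m in ring.members:
        for atom in lookup[m].atoms:
            positions.append(atom.position)
            masses.append(atom.mass)
    pts = np.stack(positions)
    w = np.asarray(masses, dtype=float)
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def analyze_frames(
    frames: Sequence[Frame],
    params: TIP3PParams = TIP3PParams(),
    cutoff: float = DEFAULT_OO_CUTOFF,
    minimum_image: bool = False,
    com_mode: str = "all",
) -> list[WaterRing]:
    """Run graph construction + ring enumeration + COM over many frames.

    Rings are deduplicated within a frame only: the same water cycle seen in
    several frames yields one record per frame, each tagged with frame_id.
    """
    if not frames:
        raise ValueError("analyze_frames needs at least one frame")
    rings: list[WaterRing] = []
    for frame in frames:
        try:
            graph = build_hbond_graph(frame, params, cutoff, minimum_image)
            for ring in enumerate_rings(graph):
                rings.append(
                    replace(
                        ring,
                        frame_id=frame.frame_id,
                        center_of_mass=ring_center_of_mass(ring, frame, com_mode),
                    )
                )
        except Exception as exc:
            raise FrameAnalysisError(f"frame {frame.frame_id}: {exc}") from exc
    return rings


def write_ring_table(rings: Sequence[WaterRing], path) -> None:
    """Delimited ring report: frame, class, members and COM coordinates."""
    lines = ["frame_id,ring_class,members,com_x,com_y,com_z"]
    for ring in rings:
        com = ring.center_of_mass
        if com is None:
            raise ValueError("ring without center_of_mass; run analyze_frames")
        members = "-".join(str(m) for m in ring.members)
        lines.append(
            f"{ring.frame_id},{ring.ring_class},{members},"
            f"{com[0]:.3f},{com[1]:.3f},{com[2]:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ring_com_pdb(rings: Sequence[WaterRing], path) -> None:
    """Pseudo-atom PDB of ring COMs (one HETATM per ring, resname = class)."""
    lines = []
    for serial, ring in enumerate(rings, start=1):
        com = ring.center_of_mass
        if com is None:
            raise ValueError("ring without center_of_mass; run analyze_frames")
        lines.append(
            f"HETATM{serial % 100000:5d}  X   {ring.ring_class:<4s}"
            f"R{serial % 10000:4d}    "
            f"{com[0]:8.3f}{com[1]:8.3f}{com[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'X':>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ring_com_pdb(path) -> np.ndarray:
    """Read back the COM pseudo-atom PDB written by :func:`write_ring_com_pdb`."""
    points = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(("HETATM", "ATOM")):
            points.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if not points:
        raise ValueError(f"{path}: no COM records found")
    return np.asarray(points)
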