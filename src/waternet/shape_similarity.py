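"""Alignment-free shape descriptors and similarity for 3D point sets.

A point cloud is summarized by the first three moments (mean, population
standard deviation, signed cube-root skew) of its distance distributions to
four reference points: the centroid (ctd), the point closest to the centroid
(cst), the point farthest from the centroid (fct), and the point farthest
from fct (ftf) — a 12-component vector. Two clouds are compared with
S = 1 / (1 + mean absolute moment difference), in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._util import round_half_away

__all__ = [
    "USRDescriptor",
    "DegenerateInputError",
    "REFERENCE_ORDER",
    "usr_descriptor",
    "usr_similarity",
    "twn_ligand_shape_similarity",
    "write_descriptor_csv",
]

#: Frozen reference-point order of the 12-vector. Both descriptors of a
#: comparison must use the same order; this one is fixed package-wide.
REFERENCE_ORDER = ("ctd", "cst", "fct", "ftf")


class DegenerateInputError(ValueError):
    """Too few points to form a meaningful shape descriptor."""


@dataclass(frozen=True)
class USRDescriptor:
    """12 shape moments, (mu1, mu2, mu3) per reference point in REFERENCE_ORDER."""

    moments: tuple[float, ...]
    n_points: int

    def __post_init__(self) -> None:
        if len(self.moments) != 12:
            raise ValueError(f"expected 12 moments, got {len(self.moments)}")
        for k in range(0, 12, 3):
            if self.moments[k] < 0 or self.moments[k + 1] < 0:
                raise ValueError("mu1 and mu2 must be non-negative")

    @property
    def degenerate(self) -> bool:
        """True when built from fewer than 4 points."""
        return self.n_points < 4


def _moments(distances: np.ndarray) -> tuple[float, float, float]:
    mu1 = float(distances.mean())
    centered = distances - mu1
    mu2 = float(np.sqrt((centered**2).mean()))
    third = float((centered**3).mean())
    mu3 = float(np.cbrt(third))
    return mu1, mu2, mu3


def usr_descriptor(points: Sequence) -> USRDescriptor:
    """Shape descriptor of a 3D point set.

    Ties for closest/farthest reference points are broken by lowest point
    index, so the descriptor is deterministic. Fewer than 2 points is an
    error; 2-3 points yield a descriptor flagged degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {pts.shape}")
    n = pts.shape[0]
    if n < 2:
        raise DegenerateInputError(f"need at least 2 points, got {n}")
    ctd = pts.mean(axis=0)
    d_ctd = np.linalg.norm(pts - ctd, axis=1)
    cst = pts[int(np.argmin(d_ctd))]  # argmin/argmax return the first index on ties
    fct = pts[int(np.argmax(d_ctd))]
    d_fct = np.linalg.norm(pts - fct, axis=1)
    ftf = pts[int(np.argmax(d_fct))]

    moments: list[float] = []
    for ref in (ctd, cst, fct, ftf):
        moments.extend(_moments(np.linalg.norm(pts - ref, axis=1)))
    return USRDescriptor(moments=tuple(moments), n_points=n)


def usr_similarity(q: USRDescriptor, i: USRDescriptor) -> float:
    """S = 1 / (1 + mean |moment difference|); 1 iff descriptors identical."""
    mq = np.asarray(q.moments)
    mi = np.asarray(i.moments)
    return float(1.0 / (1.0 + np.abs(mq - mi).mean()))


def twn_ligand_shape_similarity(
    rings: Sequence,
    ligand_atoms: Sequence,
    include_hydrogens: bool = False,
    max_dist: Optional[float] = None,
) -> float:
    """Ring-COM cloud vs. ligand atom cloud similarity, as a percentage.

    Ring COMs (pooled over frames and ring classes) form one point set, the
    ligand's heavy atoms the other; returns 100*S rounded to 1 decimal.
    ``max_dist`` optionally keeps only rings whose COM lies within that
    distance of some ligand heavy atom.
    """
    lig_pts = [
        np.asarray(a.position, dtype=float)
        for a in ligand_atoms
        if include_hydrogens or a.element.upper() != "H"
    ]
    if len(lig_pts) < 4:
        raise DegenerateInputError(
            f"ligand side has {len(lig_pts)} usable atoms; need >= 4"
        )
    lig = np.stack(lig_pts)

    coms = []
    for ring in rings:
        com = getattr(ring, "center_of_mass", None)
        if com is None:
            raise ValueError("ring has no center_of_mass; compute COMs first")
        coms.append(np.asarray(com, dtype=float))
    if max_dist is not None:
        coms = [
            c for c in coms
            if float(np.linalg.norm(lig - c, axis=1).min()) <= max_dist
        ]
    if len(coms) < 4:
        raise DegenerateInputError(
            f"ring side has {len(coms)} centers of mass; need >= 4"
        )
    score = usr_similarity(usr_descriptor(np.stack(coms)), usr_descriptor(lig))
    return round_half_away(100.0 * score, 1)


def write_descriptor_csv(descriptors: dict[str, USRDescriptor], path) -> None:
    """Write labeled descriptors as a 12-moment CSV table."""
    header = ",".join(
        f"mu{m}_{ref}" for ref in REFERENCE_ORDER for m in (1, 2, 3)
    )
    lines = ["label," + header]
    for label, desc in descriptors.items():
        values = ",".join(f"{m:.6f}" for m in desc.moments)
        lines.append(f"{label},{values}")
    Path(path).write_text("\n".join(lines) + "\n")
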