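"""Named spherical binding-site regions and per-region ring statistics.

A ring is assigned to the region whose sphere contains its center of mass;
when several spheres contain it, the nearest center wins (declaration order
breaks exact ties). Rings falling outside every sphere are excluded from the
ratio denominator, so the per-region percentages always total 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._util import as_vec3, round_half_away

__all__ = [
    "Region",
    "RegionSpec",
    "TWNDistribution",
    "assign_region",
    "distribution",
    "make_region_spec_from_ligand",
]


@dataclass(frozen=True)
class Region:
    name: str
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", as_vec3(self.center, f"center of {self.name!r}"))
        if not self.radius > 0:
            raise ValueError(f"region {self.name!r}: radius must be > 0, got {self.radius}")

    def contains(self, point: np.ndarray) -> bool:
        return float(np.linalg.norm(point - self.center)) <= self.radius


@dataclass
class RegionSpec:
    """Ordered collection of uniquely named spherical regions."""

    regions: list[Region]

    def __post_init__(self) -> None:
        self.regions = list(self.regions)
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]


def assign_region(point, spec: RegionSpec) -> Optional[str]:
    """Name of the region containing ``point``, nearest-center on overlap.

    Returns ``None`` when no sphere contains the point. Exact distance ties go
    to the earlier-declared region.
    """
    if not len(spec):
        raise ValueError("region spec is empty")
    point = as_vec3(point, "point")
    best_name: Optional[str] = None
    best_dist = np.inf
    for region in spec:
        d = float(np.linalg.norm(point - region.center))
        if d <= region.radius and d < best_dist:
            best_name, best_dist = region.name, d
    return best_name


@dataclass
class TWNDistribution:
    """Per-region ring counts and percentage table.

    ``ratios`` are percentages of the assigned total, rounded half-away-from-
    zero to 1 decimal; unassigned rings are counted separately and excluded
    from the denominator.
    """

    counts: dict[str, int]
    ratios: dict[str, float]
    total: int
    unassigned: int
    empty_warning: bool = field(default=False)

    def to_rows(self) -> list[tuple[str, int, float]]:
        return [(name, self.counts[name], self.ratios[name]) for name in self.counts]

    def to_csv(self) -> str:
        lines = ["region,number,ratio_pct"]
        for name, count, ratio in self.to_rows():
            lines.append(f"{name},{count},{ratio:.1f}")
        lines.append(f"Total,{self.total},{100.0 if self.total else 0.0:.1f}")
        return "\n".join(lines) + "\n"

    def pretty(self) -> str:
        width = max([len(n) for n in self.counts] + [len("Region")])
        lines = [f"{'Region':<{width}}  {'Number':>6}  {'Ratio(%)':>8}"]
        for name, count, ratio in self.to_rows():
            lines.append(f"{name:<{width}}  {count:>6d}  {ratio:>8.1f}")
        lines.append(
            f"{'Total':<{width}}  {self.total:>6d}  {100.0 if self.total else 0.0:>8.1f}"
        )
        if self.unassigned:
            lines.append(f"(unassigned rings excluded: {self.unassigned})")
        return "\n".join(lines)


def distribution(rings: Sequence, spec: RegionSpec) -> TWNDistribution:
    """Tally ring centers of mass into regions and compute the ratio table.

    ``rings`` may be any sequence of objects with a ``center_of_mass``
    attribute (3-vector). Rings outside every region increment ``unassigned``
    only.
    """
    counts = {name: 0 for name in spec.names}
    unassigned = 0
    for ring in rings:
        com = getattr(ring, "center_of_mass", None)
        if com is None:
            raise ValueError("ring has no center_of_mass; compute COMs first")
        name = assign_region(com, spec)
        if name is None:
            unassigned += 1
        else:
            counts[name] += 1
    total = sum(counts.values())
    if total > 0:
        ratios = {
            name: round_half_away(100.0 * count / total, 1)
            for name, count in counts.items()
        }
        warning = False
    else:
        ratios = {name: 0.0 for name in counts}
        warning = True
    return TWNDistribution(
        counts=counts, ratios=ratios, total=total, unassigned=unassigned,
        empty_warning=warning,
    )


def make_region_spec_from_ligand(
    ligand_atoms: Sequence,
    fragments: dict[str, Iterable[int]],
    radius: float = 3.0,
) -> RegionSpec:
    """Build spherical regions centered on ligand-fragment centroids.

    ``fragments`` maps region name -> indices into ``ligand_atoms``; each
    region gets the unweighted centroid of those atoms and a common radius.
    """
    regions = []
    for name, indices in fragments.items():
        idx = list(indices)
        if not idx:
            raise ValueError(f"fragment {name!r} has no atom indices")
        pts = np.stack([as_vec3(ligand_atoms[i].position) for i in idx])
        regions.append(Region(name=name, center=pts.mean(axis=0), radius=radius))
    return RegionSpec(regions)
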