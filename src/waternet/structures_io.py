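"""Coordinate I/O: PDB snapshot parsing/writing and region-config loading.

The parser is deliberately strict and line-oriented so that malformed input
is reported with its line number, water residues are validated to contain
exactly one oxygen and two hydrogens, and multi-MODEL files map one MODEL to
one :class:`Frame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._util import as_vec3
from .site_regions import Region, RegionSpec

__all__ = [
    "Atom",
    "WaterMolecule",
    "TIP3PParams",
    "Frame",
    "ATOMIC_MASSES",
    "DEFAULT_WATER_RESNAMES",
    "PDBFormatError",
    "WaterValidationError",
    "RegionConfigError",
    "parse_frame",
    "parse_frames",
    "write_pdb",
    "load_region_spec",
    "write_region_spec",
]

#: Masses in Da for the elements this toolkit expects to encounter.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}

#: Residue names recognized as water across common PDB dialects.
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3"})


class PDBFormatError(ValueError):
    """A PDB record could not be parsed; carries the offending line number."""


class WaterValidationError(ValueError):
    """A water residue does not have exactly 1 O + 2 H, or bad geometry."""


class RegionConfigError(ValueError):
    """The region configuration file is malformed or inconsistent."""


def element_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"no mass tabulated for element {element!r}") from None


@dataclass
class Atom:
    """One atom: element, label, position (Å) and residue bookkeeping."""

    element: str
    name: str
    position: np.ndarray
    residue_name: str
    residue_id: int
    mass: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be non-empty")
        self.position = as_vec3(self.position, f"position of atom {self.name!r}")
        if self.mass is None:
            self.mass = element_mass(self.element)
        if not self.mass > 0:
            raise ValueError(f"atom mass must be positive, got {self.mass}")


@dataclass
class WaterMolecule:
    """A rigid three-site water: one oxygen and two hydrogens."""

    index: int
    oxygen: Atom
    hydrogen1: Atom
    hydrogen2: Atom

    def __post_init__(self) -> None:
        if self.oxygen.element.upper() != "O":
            raise WaterValidationError(
                f"water {self.index}: oxygen site has element {self.oxygen.element!r}"
            )
        for h in (self.hydrogen1, self.hydrogen2):
            if h.element.upper() != "H":
                raise WaterValidationError(
                    f"water {self.index}: hydrogen site has element {h.element!r}"
                )
            d = float(np.linalg.norm(h.position - self.oxygen.position))
            if not 0.5 < d < 1.5:
                raise WaterValidationError(
                    f"water {self.index}: O-H distance {d:.3f} Å outside (0.5, 1.5)"
                )

    @property
    def positions(self) -> np.ndarray:
        """(3, 3) array of O, H1, H2 positions."""
        return np.stack(
            [self.oxygen.position, self.hydrogen1.position, self.hydrogen2.position]
        )

    @property
    def atoms(self) -> tuple[Atom, Atom, Atom]:
        return (self.oxygen, self.hydrogen1, self.hydrogen2)


@dataclass(frozen=True)
class TIP3PParams:
    """Rigid 3-site water interaction parameters and the H-bond criterion.

    Charges in e, A in kcal·Å¹²·mol⁻¹, C in kcal·Å⁶·mol⁻¹; the Coulomb
    prefactor converts e²/Å to kcal·mol⁻¹. A water pair counts as
    hydrogen-bonded when its pair energy is at or below
    ``hbond_energy_criterion`` (kcal·mol⁻¹).
    """

    q_O: float = -0.834
    q_H: float = 0.417
    A: float = 582000.0
    C: float = 595.0
    coulomb_constant: float = 332.0636
    hbond_energy_criterion: float = -2.25

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if not self.q_O < 0 < self.q_H:
            raise ValueError(f"expected q_O < 0 < q_H, got {self.q_O}, {self.q_H}")
        if not self.hbond_energy_criterion < 0:
            raise ValueError(
                f"H-bond criterion must be negative, got {self.hbond_energy_criterion}"
            )

    @property
    def charges(self) -> tuple[float, float, float]:
        """Site charges in O, H1, H2 order."""
        return (self.q_O, self.q_H, self.q_H)


@dataclass
class Frame:
    """One coordinate snapshot: waters + protein atoms + optional ligand/box."""

    waters: list[WaterMolecule]
    protein_atoms: list[Atom] = field(default_factory=list)
    ligand_atoms: list[Atom] = field(default_factory=list)
    box: Optional[np.ndarray] = None
    frame_id: int = 1

    def __post_init__(self) -> None:
        indices = [w.index for w in self.waters]
        if len(set(indices)) != len(indices):
            raise ValueError(f"frame {self.frame_id}: duplicate water indices")
        if self.box is not None:
            self.box = as_vec3(self.box, "box")
            if not np.all(self.box > 0):
                raise ValueError(f"box lengths must be positive, got {self.box}")

    @property
    def water_by_index(self) -> dict[int, WaterMolecule]:
        return {w.index: w for w in self.waters}

    def oxygen_positions(self) -> np.ndarray:
        if not self.waters:
            return np.empty((0, 3))
        return np.stack([w.oxygen.position for w in self.waters])


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    """Infer the element from a PDB atom name when columns 77-78 are blank."""
    stripped = name.strip()
    letters = "".join(c for c in stripped if c.isalpha())
    if not letters:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    two = letters[:2].upper()
    if two in ATOMIC_MASSES and two not in {"CA", "NA"}:  # CA/NA ambiguous in proteins
        return two
    return letters[0].upper()


def _parse_atom_record(line: str, lineno: int) -> tuple[Atom, str, tuple]:
    try:
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21:22]
        resseq = int(line[22:26])
        icode = line[26:27]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(
            f"line {lineno}: malformed {line[:6].strip()} record: {exc}"
        ) from exc
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        element = _guess_element(name)
    element = element.capitalize() if len(element) > 1 else element.upper()
    atom = Atom(
        element=element,
        name=name,
        position=np.array([x, y, z]),
        residue_name=resname,
        residue_id=resseq,
    )
    return atom, resname, (chain, resseq, icode, resname)


def _build_water(residue_key, atoms: list[Atom], index: int) -> WaterMolecule:
    oxygens = [a for a in atoms if a.element.upper() == "O"]
    hydrogens = [a for a in atoms if a.element.upper() == "H"]
    resid = atoms[0].residue_id
    if len(oxygens) != 1 or len(hydrogens) != 2 or len(atoms) != 3:
        raise WaterValidationError(
            f"water residue {atoms[0].residue_name} {resid}: expected 1 O + 2 H, "
            f"found {len(oxygens)} O, {len(hydrogens)} H, {len(atoms)} atoms total"
        )
    return WaterMolecule(index=index, oxygen=oxygens[0], hydrogen1=hydrogens[0], hydrogen2=hydrogens[1])


def parse_frames(
    path,
    water_residue_names: Iterable[str] = DEFAULT_WATER_RESNAMES,
    ligand_residue_names: Iterable[str] = ("LIG",),
) -> list[Frame]:
    """Parse a (possibly multi-MODEL) PDB file into a list of frames.

    Water residues become :class:`WaterMolecule` entries (validated 1 O + 2 H),
    ligand residues go to ``ligand_atoms``, every other heavy atom to
    ``protein_atoms``. CRYST1 box lengths are attached to every frame.
    """
    path = Path(path)
    water_set = {n.upper() for n in water_residue_names}
    ligand_set = {n.upper() for n in ligand_residue_names}

    text = path.read_text()
    if not text.strip():
        raise PDBFormatError(f"{path}: empty PDB file")

    box: Optional[np.ndarray] = None
    frames: list[Frame] = []
    # per-model accumulation; waters keyed by residue identity, in file order
    model_id = None
    water_groups: dict[tuple, list[Atom]] = {}
    protein_atoms: list[Atom] = []
    ligand_atoms: list[Atom] = []

    def flush(fid: int) -> None:
        waters = [
            _build_water(key, atoms, index)
            for index, (key, atoms) in enumerate(water_groups.items())
        ]
        frames.append(
            Frame(
                waters=waters,
                protein_atoms=list(protein_atoms),
                ligand_atoms=list(ligand_atoms),
                box=box,
                frame_id=fid,
            )
        )
        water_groups.clear()
        protein_atoms.clear()
        ligand_atoms.clear()

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "CRYST1":
            try:
                box = np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                )
            except ValueError as exc:
                raise PDBFormatError(f"line {lineno}: malformed CRYST1: {exc}") from exc
        elif record == "MODEL":
            try:
                model_id = int(line.split()[1])
            except (IndexError, ValueError):
                model_id = len(frames) + 1
        elif record == "ENDMDL":
            flush(model_id if model_id is not None else len(frames) + 1)
            model_id = None
        elif record in ("ATOM", "HETATM"):
            atom, resname, key = _parse_atom_record(line, lineno)
            if resname.upper() in water_set:
                water_groups.setdefault(key, []).append(atom)
            elif resname.upper() in ligand_set:
                ligand_atoms.append(atom)
            elif atom.element.upper() != "H":
                protein_atoms.append(atom)
            else:  # protein hydrogens are kept too; they are inert downstream
                protein_atoms.append(atom)
        # all other records (TER, END, REMARK, ...) are ignored

    if water_groups or protein_atoms or ligand_atoms:
        flush(model_id if model_id is not None else len(frames) + 1)
    if not frames:
        raise PDBFormatError(f"{path}: no coordinate records found")
    return frames


def parse_frame(
    path,
    water_residue_names: Iterable[str] = DEFAULT_WATER_RESNAMES,
    ligand_residue_names: Iterable[str] = ("LIG",),
) -> Frame:
    """Parse a single-snapshot PDB file; reject multi-MODEL input."""
    frames = parse_frames(path, water_residue_names, ligand_residue_names)
    if len(frames) != 1:
        raise PDBFormatError(
            f"{path}: expected a single snapshot but found {len(frames)} MODELs; "
            "use parse_frames for trajectories"
        )
    return frames[0]


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(
    record: str, serial: int, atom: Atom, chain: str = "A"
) -> str:
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.position
    return (
        f"{record:<6s}{serial % 100000:5d} {name:<4s} {atom.residue_name:<4s}"
        f"{chain}{atom.residue_id % 10000:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{atom.element.upper():>2s}"
    )


def write_pdb(frames: Sequence[Frame], path) -> None:
    """Write frames to a (multi-MODEL when >1) PDB file.

    The first frame's box, if any, is emitted as a CRYST1 record with 90°
    angles (orthorhombic).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("write_pdb needs at least one frame")
    lines: list[str] = []
    box = frames[0].box
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    multi = len(frames) > 1
    for frame in frames:
        if multi:
            lines.append(f"MODEL     {frame.frame_id:4d}")
        serial = 1
        for atom in frame.protein_atoms:
            lines.append(_format_atom_line("ATOM", serial, atom))
            serial += 1
        for atom in frame.ligand_atoms:
            lines.append(_format_atom_line("HETATM", serial, atom, chain="L"))
            serial += 1
        for water in frame.waters:
            for atom in water.atoms:
                lines.append(_format_atom_line("HETATM", serial, atom, chain="W"))
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Region configuration
# ---------------------------------------------------------------------------

def load_region_spec(path) -> RegionSpec:
    """Load a region spec from a flat text config.

    Format: one region per line, ``name center_x center_y center_z radius``,
    whitespace- or comma-separated; blank lines and ``#`` comments ignored.
    Declaration order is preserved (it breaks assignment ties).
    """
    path = Path(path)
    regions: list[Region] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 5:
            raise RegionConfigError(
                f"{path}:{lineno}: expected 'name x y z radius', got {raw!r}"
            )
        name = parts[0]
        if name in seen:
            raise RegionConfigError(f"{path}:{lineno}: duplicate region name {name!r}")
        seen.add(name)
        try:
            x, y, z, radius = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise RegionConfigError(f"{path}:{lineno}: {exc}") from exc
        if not radius > 0:
            raise RegionConfigError(
                f"{path}:{lineno}: region {name!r} radius must be > 0, got {radius}"
            )
        regions.append(Region(name=name, center=np.array([x, y, z]), radius=radius))
    if not regions:
        raise RegionConfigError(f"{path}: no regions declared")
    return RegionSpec(regions)


def write_region_spec(spec: RegionSpec, path) -> None:
    lines = ["# name center_x center_y center_z radius"]
    for region in spec.regions:
        c = region.center
        lines.append(
            f"{region.name} {c[0]:.3f} {c[1]:.3f} {c[2]:.3f} {region.radius:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
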