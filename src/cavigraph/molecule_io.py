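"""Molecule and trajectory I/O.

Reads PDB files (optionally multi-model) and DCD trajectories into
:class:`MolecularFrame` objects, attaches van der Waals radii and the
four-class residue chemistry table, and writes cavity-graph nodes back out
as pseudo-atom PDB files for inspection in any molecular viewer.

Coordinates are in Angstrom, right-handed, exactly as stored in the PDB;
no recentering is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Bondi-style van der Waals radii (Angstrom). The lookup is case-insensitive
# and total over the elements common in protein models.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70  # fallback for unknown elements (carbon-like)

# Four-category chemistry of the 20 standard amino acids (Venn-diagram style
# classification: hydrophobic / polar / positively / negatively charged).
DEFAULT_RESIDUE_CLASSES: dict[str, str] = {
    **{r: "hydrophobic" for r in
       ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY")},
    **{r: "polar" for r in ("SER", "THR", "CYS", "TYR", "ASN", "GLN")},
    **{r: "positive" for r in ("LYS", "ARG", "HIS")},
    **{r: "negative" for r in ("ASP", "GLU")},
}

RESIDUE_CLASS_NAMES = ("hydrophobic", "polar", "positive", "negative")

# residue names treated as solvent and dropped by default
_SOLVENT_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC", "DOD"}


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element symbol (case-insensitive).

    Unknown elements fall back to the carbon radius with a warning.
    """
    r = VDW_RADII.get(element.strip().upper())
    if r is None:
        warnings.warn(
            f"unknown element {element!r}: using fallback vdW radius "
            f"{DEFAULT_VDW_RADIUS} A",
            stacklevel=2,
        )
        return DEFAULT_VDW_RADIUS
    return r


@dataclass(frozen=True)
class Atom:
    """One atom: identity, position and van der Waals radius."""

    serial: int
    element: str
    residue_name: str
    residue_number: int
    chain: str
    center: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")
        if not np.all(np.isfinite(self.center)):
            raise ValueError(f"non-finite atom center {self.center}")


class MolecularFrame:
    """One snapshot of a molecule: atoms plus cached coordinate arrays.

    Array views (``coords``, ``radii``, ``residue_numbers`` ...) are the
    working representation for the geometry stages; the ``atoms`` sequence
    retains full per-atom identity.
    """

    def __init__(self, atoms: Sequence[Atom], frame_index: int = 0) -> None:
        if len(atoms) == 0:
            raise ValueError("a MolecularFrame needs at least one atom")
        self.frame_index = int(frame_index)
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self.coords = np.array([a.center for a in self.atoms], dtype=float)
        self.radii = np.array([a.vdw_radius for a in self.atoms], dtype=float)
        self.residue_numbers = np.array(
            [a.residue_number for a in self.atoms], dtype=int
        )
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.chains = np.array([a.chain for a in self.atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<MolecularFrame t={self.frame_index} atoms={len(self)}>"

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box of the atom centers (min, max)."""
        return self.coords.min(axis=0), self.coords.max(axis=0)

    @property
    def bbox_diagonal(self) -> float:
        lo, hi = self.bounds
        return float(np.linalg.norm(hi - lo))

    def residue_ids(self, chain_qualified: bool = False) -> set:
        """Set of residue identifiers present in the frame.

        By default residues are identified by residue number alone (the form
        used in queries like ``171&190``); ``chain_qualified=True`` returns
        ``(chain, residue_number)`` pairs for multichain inputs.
        """
        if chain_qualified:
            return {(a.chain, a.residue_number) for a in self.atoms}
        return {a.residue_number for a in self.atoms}


@dataclass
class ResidueClassTable:
    """Mapping 3-letter residue code -> chemistry class.

    Total over the 20 standard residues; overridable entry by entry.
    Unknown residue names classify as hydrophobic (the least assuming
    default for synthetic or modified residues).
    """

    mapping: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_CLASSES)
    )

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - set(RESIDUE_CLASS_NAMES)
        if bad:
            raise ValueError(f"unknown residue classes: {sorted(bad)}")

    def classify(self, residue_name: str) -> str:
        return self.mapping.get(residue_name.strip().upper(), "hydrophobic")


def _frame_from_atom_array(array, frame_index: int, exclude_solvent: bool) -> MolecularFrame:
    import biotite.structure as struc  # local: keep import cost off the hot path

    keep = np.ones(array.array_length(), dtype=bool)
    if exclude_solvent:
        keep &= ~np.isin(array.res_name, list(_SOLVENT_RESNAMES))
        keep &= ~struc.filter_monoatomic_ions(array)
    # altloc beyond "A" is already discarded by the reader (altloc_id filter)
    array = array[keep]
    if array.array_length() == 0:
        raise ValueError("no atoms left after solvent exclusion")

    atoms = []
    for i in range(array.array_length()):
        el = str(array.element[i])
        atoms.append(
            Atom(
                serial=i + 1,
                element=el,
                residue_name=str(array.res_name[i]),
                residue_number=int(array.res_id[i]),
                chain=str(array.chain_id[i]) or "A",
                center=tuple(float(x) for x in array.coord[i]),
                vdw_radius=vdw_radius(el),
            )
        )
    return MolecularFrame(atoms, frame_index=frame_index)


def read_pdb(
    path: str | Path,
    exclude_solvent: bool = True,
    model: int | None = None,
) -> list[MolecularFrame]:
    """Read a (possibly multi-model) PDB file.

    Returns one :class:`MolecularFrame` per MODEL record (a single frame if
    the file has none). Waters and monoatomic ions are excluded by default;
    hydrogens, if present, are kept. Radii come from the element table.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")

    if model is not None:
        array = pdb.get_structure(model=model, altloc="first")
        return [_frame_from_atom_array(array, model - 1, exclude_solvent)]

    frames = []
    for m in range(1, n_models + 1):
        array = pdb.get_structure(model=m, altloc="first")
        frames.append(_frame_from_atom_array(array, m - 1, exclude_solvent))
    return frames


def read_trajectory(
    topology_path: str | Path,
    trajectory_path: str | Path,
    start: int | None = None,
    stop: int | None = None,
    stride: int | None = None,
    exclude_solvent: bool = True,
) -> list[MolecularFrame]:
    """Read a trajectory (e.g. DCD) against a PDB topology.

    Frames come back in file order, restricted by ``start:stop:stride``.
    Atom identity (element, residue, chain) is taken from the topology and
    is identical across frames; only coordinates change.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses masses noisily
        u = mda.Universe(str(topology_path), str(trajectory_path))

    n_top = len(u.atoms)
    n_traj = u.trajectory.n_atoms
    if n_top != n_traj:  # pragma: no cover - MDAnalysis usually raises first
        raise ValueError(
            f"atom count mismatch: topology has {n_top}, trajectory has {n_traj}"
        )

    template = read_pdb(topology_path, exclude_solvent=exclude_solvent)[0]
    if len(template) != n_top:
        # solvent was stripped from the template: select the same subset
        sel_idx = [a.serial - 1 for a in template.atoms]
    else:
        sel_idx = list(range(n_top))

    frames = []
    for t, _ts in enumerate(u.trajectory[slice(start, stop, stride)]):
        pos = u.atoms.positions[sel_idx].astype(float)
        atoms = [
            Atom(
                serial=a.serial,
                element=a.element,
                residue_name=a.residue_name,
                residue_number=a.residue_number,
                chain=a.chain,
                center=tuple(pos[i]),
                vdw_radius=a.vdw_radius,
            )
            for i, a in enumerate(template.atoms)
        ]
        frames.append(MolecularFrame(atoms, frame_index=t))
    return frames


def write_pdb(frames: MolecularFrame | Sequence[MolecularFrame], path: str | Path) -> None:
    """Write one frame (or several, as MODEL blocks) to a PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(frames, MolecularFrame):
        frames = [frames]

    arrays = []
    for frame in frames:
        n = len(frame)
        arr = struc.AtomArray(n)
        arr.coord = frame.coords.astype(np.float32)
        arr.chain_id[:] = frame.chains
        arr.res_id[:] = frame.residue_numbers
        arr.res_name[:] = frame.residue_names
        arr.element[:] = [a.element for a in frame.atoms]
        arr.atom_name[:] = [a.element for a in frame.atoms]
        arrays.append(arr)

    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def write_cavity_spheres(graphs: Iterable, path: str | Path) -> None:
    """Write cavity-graph nodes as pseudo-atoms (one HETATM per node).

    The B-factor column carries the node radius (its distance to the
    molecular surface) and the residue number carries the graph id, so
    cavities can be colored and sized in a standard viewer. An empty graph
    list produces a header-only file.
    """
    lines = ["REMARK   cavity graph nodes: B-factor = node radius, resSeq = graph id"]
    serial = 0
    for g in graphs:
        for node in g.nodes:
            serial += 1
            x, y, z = node.position
            lines.append(
                f"HETATM{serial % 100000:5d}  CAV CAV A{g.graph_id % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{node.radius:6.2f}"
                f"          {'C':>2s}  "
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cavity_spheres(path: str | Path) -> list[tuple[int, np.ndarray, float]]:
    """Read back a pseudo-atom cavity file: (graph_id, position, radius) rows."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith("HETATM"):
            continue
        gid = int(line[22:26])
        pos = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        radius = float(line[60:66])
        rows.append((gid, pos, radius))
    return rows
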