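"""Synthetic molecules and trajectories with known cavity ground truth.

Every generator returns a frame (or list of frames) plus a ground-truth
dictionary describing what a correct detection must find: cavity counts,
the region the cavity nodes must occupy, lining residue labels and, for the
breathing trajectory, the open/closed schedule. Generators can also write
their output as (multi-model) PDB with a JSON ground-truth sidecar, so each
fixture round-trips through the regular I/O path.

All fixture atoms are carbons (vdW 1.70 A) for analytic tractability; with
the default solvent probe R = 1.4 A an atom's solvent-accessible sphere has
radius 3.1 A. Residue labels are drawn from the four chemistry classes so
profile code is exercised: lining VAL (hydrophobic), bulk GLY (hydrophobic),
shells SER (polar), lids LYS (positive).
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import numpy as np

from .molecule_io import Atom, MolecularFrame, write_pdb

_CARBON = 1.70
_PROBE = 1.4
_SAS = _CARBON + _PROBE  # 3.1 A: inflated sphere radius of every fixture atom
_SPACING = 1.8  # lattice spacing; well below 2*_SAS, so slabs are watertight


def _atom(i: int, pos, res_num: int, res_name: str) -> Atom:
    return Atom(
        serial=i + 1,
        element="C",
        residue_name=res_name,
        residue_number=res_num,
        chain="A",
        center=(float(pos[0]), float(pos[1]), float(pos[2])),
        vdw_radius=_CARBON,
    )


def _frame(positions, res_nums, res_names, frame_index=0) -> MolecularFrame:
    atoms = [
        _atom(i, p, rn, rna)
        for i, (p, rn, rna) in enumerate(zip(positions, res_nums, res_names))
    ]
    return MolecularFrame(atoms, frame_index=frame_index)


def make_lone_atom() -> tuple[MolecularFrame, dict]:
    """A single carbon: a convex surface, zero cavities."""
    frame = _frame([(0.0, 0.0, 0.0)], [1], ["GLY"])
    return frame, {"n_atoms": 1, "n_cavities": 0}


def make_convex_cluster(n: int = 3) -> tuple[MolecularFrame, dict]:
    """A compact cluster of n heavily overlapping carbons.

    Atom centers are the n lattice points nearest the origin at spacing
    1.5 A; with inflated spheres of 3.1 A the union is convex up to shallow
    creases no outward ray can re-enter. Ground truth: zero cavities.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = 3
    grid = np.array(
        list(itertools.product(range(-m, m + 1), repeat=3)), dtype=float
    ) * 1.5
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0],
                        np.linalg.norm(grid, axis=1)))
    pts = grid[order][:n]
    frame = _frame(pts, [1] * n, ["GLY"] * n)
    return frame, {"n_atoms": n, "n_cavities": 0}


def _slab_positions(width: float, z_levels, spacing: float):
    half = spacing * np.floor((width / 2.0) / spacing)
    axis = np.arange(-half, half + spacing / 2, spacing)
    return [
        (x, y, z) for z in z_levels for x in axis for y in axis
    ]


def make_slab_pocket(
    width: float = 16.2,
    depth: float = 4.8,
    mouth: float = 4.5,
    lining_residue: int = 7,
    two_sided: bool = False,
    spacing: float = _SPACING,
) -> tuple[MolecularFrame, dict]:
    """A slab of atoms with a spherical depression: exactly one pocket.

    The pocket is carved by removing all atoms within ``depth`` (the carve
    sphere radius) of a center sunk below the top face so that the opening
    at the face has radius ``mouth`` — a concave patch with a narrow mouth.
    Atoms near the carve center get residue ``lining_residue`` (name VAL);
    everything farther gets residue 99 (GLY). The lining label radius is the
    analytic bound on what the skeleton's D_g = 3R distance object can ever
    reach (D_g + r + R from any point of the pocket void), so a correct
    assignment is a subset of the lining by construction.

    ``two_sided=True`` carves a second, identical pocket into the bottom
    face (lining residue ``lining_residue + 1``, name VAL), with enough slab
    between the two voids that they stay disconnected.
    """
    if mouth >= depth:
        raise ValueError("mouth radius must be smaller than the carve radius")
    sink = float(np.sqrt(depth**2 - mouth**2))
    # slab thickness: at least one intact layer below the carve bottom
    n_layers = int(np.ceil((sink + depth) / spacing)) + 1
    if two_sided:
        n_layers = 2 * n_layers - 1
    z_levels = [-i * spacing for i in range(n_layers)]
    positions = np.array(_slab_positions(width, z_levels, spacing))

    c1 = np.array([0.0, 0.0, -sink])
    centers = [c1]
    if two_sided:
        centers.append(np.array([0.0, 0.0, z_levels[-1] + sink]))

    keep = np.ones(len(positions), dtype=bool)
    for c in centers:
        keep &= np.linalg.norm(positions - c, axis=1) >= depth
    positions = positions[keep]

    # void extent: pocket points with f < 0 lie within depth - SAS (+ lattice
    # bulge) of the carve center radially, and the mouth column reaches about
    # 1.2 A above the face: a bound on where cavity nodes can sit
    void_bound = float(np.hypot(depth - _SAS + 0.4, sink + 1.2))
    label_radius = 3.0 * _PROBE + _SAS + void_bound  # D_g + (r+R) + void

    res_nums, res_names = [], []
    for p in positions:
        d = [float(np.linalg.norm(p - c)) for c in centers]
        j = int(np.argmin(d))
        if d[j] <= label_radius:
            res_nums.append(lining_residue + j)
            res_names.append("VAL")
        else:
            res_nums.append(99)
            res_names.append("GLY")

    frame = _frame(positions, res_nums, res_names)
    gt = {
        "n_atoms": len(positions),
        "n_cavities": len(centers),
        "pocket_centers": [list(map(float, c)) for c in centers],
        "carve_radius": depth,
        "node_radius_bound": float(void_bound),
        "lining_residues": [lining_residue + j for j in range(len(centers))],
        "lining_atom_count": int(sum(r != 99 for r in res_nums)),
        "bulk_residue": 99,
    }
    return frame, gt


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_hollow_shell(
    r_inner: float = 3.4, r_outer: float = 9.6
) -> tuple[MolecularFrame, dict]:
    """A closed spherical shell of atoms with an empty interior.

    Atom centers sit on the mid-sphere of radius (r_inner + r_outer)/2 at
    ~1.8 A spacing (deterministic Fibonacci lattice, so the atom count is a
    pure function of the radii). With the default probe the interior void is
    a ball of radius about r_c - 3.1; ground truth is a single internal
    cavity whose nodes lie within ``r_inner`` of the center.
    """
    r_c = 0.5 * (r_inner + r_outer)
    if r_c <= _SAS:
        raise ValueError("shell too small to enclose a void")
    n = max(int(round(4.0 * np.pi * r_c**2 / _SPACING**2)), 12)
    positions = r_c * _fibonacci_sphere(n)
    frame = _frame(positions, [5] * n, ["SER"] * n)
    gt = {
        "n_atoms": n,
        "n_cavities": 1,
        "center": [0.0, 0.0, 0.0],
        "shell_radius": float(r_c),
        "void_radius": float(r_c - _SAS),
        "node_radius_bound": float(r_inner),
        "shell_residue": 5,
    }
    return frame, gt


def make_breathing_trajectory(
    n_frames: int = 10,
    open_frames: tuple[int, ...] = (0, 1, 2, 3, 8, 9),
    lid_displacement: float = 25.0,
    lining_residue: int = 7,
) -> tuple[list[MolecularFrame], dict]:
    """A slab pocket whose depression is filled by a lid group of atoms in
    closed frames and vacated in open frames.

    The lid is a column of five carbons (residue 50, LYS) along the pocket
    axis that overfills the void when in place; in ``open_frames`` the whole
    group is translated by ``lid_displacement`` along +z. Ground truth: the
    lining-residue cavity exists exactly in the open frames, so the
    presence fraction of the lining-residue query is
    ``len(open_frames) / n_frames``.
    """
    open_set = set(open_frames)
    if not open_set <= set(range(n_frames)):
        raise ValueError("open_frames must be frame indices < n_frames")

    base, gt_slab = make_slab_pocket(lining_residue=lining_residue)
    sink = -gt_slab["pocket_centers"][0][2]
    lid_z = np.array([-3.8, -2.3, -0.8, 0.7, 2.2]) + (1.67 - sink)
    n_base = len(base)

    frames = []
    schedule = []
    for t in range(n_frames):
        dz = lid_displacement if t in open_set else 0.0
        schedule.append(dz)
        atoms = list(base.atoms)
        for j, z in enumerate(lid_z):
            atoms.append(
                _atom(n_base + j, (0.0, 0.0, z + dz), 50, "LYS")
            )
        frames.append(MolecularFrame(atoms, frame_index=t))

    gt = {
        "n_frames": n_frames,
        "n_atoms": n_base + len(lid_z),
        "open_frames": sorted(open_set),
        "lid_residue": 50,
        "lid_atom_count": len(lid_z),
        "lid_displacement_schedule": schedule,
        "lining_residue": lining_residue,
        "presence_fraction": len(open_set) / n_frames,
        "slab": gt_slab,
    }
    return frames, gt


def write_fixture(frames, ground_truth: dict, pdb_path: str | Path) -> None:
    """Write a fixture as PDB (multi-model if several frames) plus a JSON
    ground-truth sidecar next to it."""
    pdb_path = Path(pdb_path)
    write_pdb(frames, pdb_path)
    sidecar = pdb_path.with_suffix(".json")
    sidecar.write_text(json.dumps(ground_truth, indent=1) + "\n")
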