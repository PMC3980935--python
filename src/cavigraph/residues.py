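"""Assign amino acids to cavity graphs and build chemical profiles.

The MST skeleton of a cavity is turned into a distance object: every point
of space within D_g (default 3R) of the skeleton belongs to the cavity's
neighborhood. An atom is assigned to the cavity when the piece of molecular
surface it contributes lies inside that neighborhood — concretely, when the
point q on the atom's inflated sphere nearest to some skeleton point s is
(a) within D_g of s and (b) actually on the molecular surface, i.e. the
atom is the maximizing contributor of the union there (f(q) <= eps_iso;
q cannot be buried inside another atom's sphere).

The cavity profile counts the contributing atoms by the chemistry class of
their parent residue (hydrophobic / polar / positive / negative) and
reports the four ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .graphs import CavityGraph
from .molecule_io import MolecularFrame, ResidueClassTable, RESIDUE_CLASS_NAMES
from .surface import EPS_ISO, SurfaceField

logger = logging.getLogger(__name__)


@dataclass
class ResidueAssignment:
    """Residues (and the atoms) whose surface lies within D_g of a cavity
    skeleton."""

    graph_id: int
    residues: set[int]
    atom_indices: set[int]


def skeleton_points(graph: CavityGraph, spacing: float = 0.7) -> np.ndarray:
    """Densified MST skeleton: all nodes plus points along each MST edge at
    the given spacing."""
    pts = [np.asarray(n.position, float) for n in graph.nodes]
    positions = graph.positions()
    for u, v, w in graph.mst_edges:
        if w <= spacing:
            continue
        m = int(np.ceil(w / spacing)) - 1
        t = np.arange(1, m + 1) / (m + 1)
        seg = positions[u][None, :] + t[:, None] * (positions[v] - positions[u])[None, :]
        pts.append(seg)
    return np.vstack([p if p.ndim == 2 else p[None, :] for p in pts])


def assign_residues(
    graph: CavityGraph,
    field: SurfaceField,
    frame: MolecularFrame,
    d_g: float | None = None,
    spacing: float | None = None,
    chain_qualified: bool = False,
) -> ResidueAssignment:
    """Atoms/residues whose surface patch intersects the skeleton's D_g
    distance object.

    ``d_g`` defaults to 3R, ``spacing`` (skeleton densification) to R/2.
    An empty result is allowed (a graph far from any surface) and logged.
    """
    R = field.model.probe_radius
    if d_g is None:
        d_g = 3.0 * R
    if spacing is None:
        spacing = R / 2.0

    skel = skeleton_points(graph, spacing=spacing)
    inflate = frame.radii + field.model.effective_probe
    tree = cKDTree(frame.coords)
    reach = d_g + float(inflate.max())

    candidates: dict[int, list[np.ndarray]] = {}
    for s, hits in zip(skel, tree.query_ball_point(skel, reach)):
        for i in hits:
            d = float(np.linalg.norm(s - frame.coords[i]))
            if abs(d - inflate[i]) > d_g:
                continue  # nearest surface point of this sphere is too far
            if d == 0.0:
                continue  # skeleton point at the atom center: buried anyway
            q = frame.coords[i] + (inflate[i] / d) * (s - frame.coords[i])
            candidates.setdefault(i, []).append(q)

    atoms: set[int] = set()
    if candidates:
        idx = sorted(candidates)
        qs = np.concatenate([np.asarray(candidates[i]) for i in idx])
        counts = [len(candidates[i]) for i in idx]
        f = field.evaluate_many(qs)
        off = 0
        for i, c in zip(idx, counts):
            # on-surface test: the atom is the maximizing contributor there
            if np.any(f[off:off + c] <= EPS_ISO):
                atoms.add(i)
            off += c

    if chain_qualified:
        residues = {(frame.atoms[i].chain, int(frame.residue_numbers[i])) for i in atoms}
    else:
        residues = {int(frame.residue_numbers[i]) for i in atoms}
    if not atoms:
        logger.info("assign_residues: graph %d has no surface within D_g=%.2f",
                    graph.graph_id, d_g)
    return ResidueAssignment(graph.graph_id, residues, atoms)


def compute_profile(
    assignment: ResidueAssignment,
    frame: MolecularFrame,
    class_table: ResidueClassTable | None = None,
) -> dict:
    """Four-class chemical profile of a cavity.

    Each contributing atom is marked by its residue's class; the profile is
    the per-class ratio of atoms (summing to 1 when any atom contributes).
    Zero contributing atoms yield all-zero ratios with ``empty=True``.
    """
    table = class_table or ResidueClassTable()
    counts = {c: 0 for c in RESIDUE_CLASS_NAMES}
    for i in assignment.atom_indices:
        counts[table.classify(str(frame.residue_names[i]))] += 1
    total = sum(counts.values())
    ratios = {
        c: (counts[c] / total if total else 0.0) for c in RESIDUE_CLASS_NAMES
    }
    return {
        "ratios": ratios,
        "atom_counts": counts,
        "total_atoms": total,
        "empty": total == 0,
    }


def annotate_graphs(
    graphs,
    field: SurfaceField,
    frame: MolecularFrame,
    d_g: float | None = None,
    class_table: ResidueClassTable | None = None,
    chain_qualified: bool = False,
) -> None:
    """Attach residue sets and profiles to every graph, in place."""
    for g in graphs:
        a = assign_residues(g, field, frame, d_g=d_g, chain_qualified=chain_qualified)
        g.residues = a.residues
        g.profile = compute_profile(a, frame, class_table)
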