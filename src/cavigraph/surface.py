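"""Implicit molecular surfaces and ray intersection.

A molecule is represented by a scalar field f that is positive inside and
negative outside; the surface is the iso-contour f = 0. Three field kinds
are supported:

``vdw``
    union of van der Waals spheres, f(p) = max_i (r_i - d_i)
``sas``
    solvent accessible surface, the vdW radii inflated by the probe radius
    R: f(p) = max_i ((r_i + R) - d_i)
``kernel``
    a Gaussian-kernel density (blobby) surface,
    f(p) = sum_i b_i * exp(-a_i * d_i^2) - T

where d_i is the distance from p to the center of atom i. The union
operator for vdw/sas is max (the standard R-function union), which makes
|f(p)| / |grad f(p)| an exact Euclidean distance to the surface of a single
sphere and a lower bound for a union — exactly what sphere tracing needs to
never overshoot.

Neighbor queries are accelerated by a uniform spatial grid with voxel edge
2*radius_max + 2*R_max; a 3x3x3 voxel neighborhood is guaranteed to contain
every atom whose sphere can reach the query point. Where the neighborhood
cannot certify the global maximum (deep outside the molecule), evaluation
falls back to a full scan so grid and brute-force evaluation agree exactly
everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .molecule_io import MolecularFrame

logger = logging.getLogger(__name__)

# numerical knobs: minimal sphere-tracing step, iso-surface tolerance,
# maximal number of ray steps
EPS_MIN = 0.05
EPS_ISO = 1e-3
N_MAX = 1024


@dataclass(frozen=True)
class SurfaceModel:
    """Which implicit function to use and its physical parameters.

    ``probe_radius`` is the solvent probe R in Angstrom (1.4 A mimics a
    water molecule). Kernel parameters follow the blobby-surface
    convention: per-atom weight ``kernel_weight`` (b_i), Gaussian decay
    ``kernel_decay`` (a_i, 1/A^2) and density threshold ``kernel_threshold``
    (T). Sign convention everywhere: f > 0 inside, f < 0 outside.
    """

    kind: str = "sas"
    probe_radius: float = 1.4
    kernel_threshold: float = 1.0
    kernel_weight: float = 4.0
    kernel_decay: float = 0.4

    def __post_init__(self) -> None:
        if self.kind not in ("vdw", "sas", "kernel"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.kind == "kernel" and self.kernel_decay <= 0:
            raise ValueError("kernel decay must be positive")

    @property
    def effective_probe(self) -> float:
        """Probe inflation actually applied to the sphere radii."""
        return self.probe_radius if self.kind == "sas" else 0.0


class SpatialGrid:
    """Uniform spatial subdivision of atoms into cubic voxels.

    Voxel edge length is 2*radius_max + 2*R_max so that any atom whose
    inflated sphere (r_i + R) can touch a point p lies in the 3x3x3 block
    of voxels around p's voxel.
    """

    def __init__(self, frame: MolecularFrame, probe_radius: float) -> None:
        self.frame = frame
        self.radius_max = float(frame.radii.max())
        self.probe_max = float(probe_radius)
        self.voxel_edge = 2.0 * self.radius_max + 2.0 * self.probe_max
        self.origin = frame.coords.min(axis=0)

        idx = np.floor((frame.coords - self.origin) / self.voxel_edge).astype(np.int64)
        self._cells: dict[tuple[int, int, int], np.ndarray] = {}
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        sorted_idx = idx[order]
        # split the sorted atom list into runs per voxel
        cut = np.nonzero(np.any(np.diff(sorted_idx, axis=0) != 0, axis=1))[0] + 1
        for chunk, key_row in zip(
            np.split(order, cut), sorted_idx[np.concatenate(([0], cut))]
        ):
            self._cells[tuple(key_row)] = np.sort(chunk)
        self._neighbor_cache: dict[tuple[int, int, int], np.ndarray] = {}
        # any atom outside the 3x3x3 block is at least one voxel edge away,
        # so its sas/vdw contribution is at most this bound
        self.out_of_block_bound = self.radius_max + self.probe_max - self.voxel_edge

    def voxel_of(self, p: np.ndarray) -> tuple[int, int, int]:
        return tuple(np.floor((np.asarray(p) - self.origin) / self.voxel_edge).astype(np.int64))

    def neighborhood(self, p: np.ndarray) -> np.ndarray:
        """Atom indices in the 3x3x3 voxel block around p (sorted, may be empty)."""
        key = self.voxel_of(p)
        cached = self._neighbor_cache.get(key)
        if cached is not None:
            return cached
        parts = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    cell = self._cells.get((key[0] + dx, key[1] + dy, key[2] + dz))
                    if cell is not None:
                        parts.append(cell)
        result = (
            np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
        )
        self._neighbor_cache[key] = result
        return result


class SurfaceField:
    """An implicit surface bound to one frame, with grid acceleration."""

    def __init__(self, model: SurfaceModel, frame: MolecularFrame,
                 grid: Optional[SpatialGrid] = None) -> None:
        self.model = model
        self.frame = frame
        # R_max for voxel sizing: the sas probe, or the kernel's effective
        # reach beyond the atom radius (conservative: 3 sigma of the Gaussian)
        if model.kind == "kernel":
            reach = 3.0 / np.sqrt(2.0 * model.kernel_decay)
            probe_for_grid = max(model.probe_radius, reach)
        else:
            probe_for_grid = model.probe_radius
        self.grid = grid if grid is not None else SpatialGrid(frame, probe_for_grid)
        self._coords = frame.coords
        self._rad = frame.radii + model.effective_probe

    # ------------------------------------------------------------------ eval

    def _values_at(self, p: np.ndarray, atom_idx: np.ndarray) -> np.ndarray:
        """Per-atom field contributions at p for the given atom indices."""
        d = np.linalg.norm(self._coords[atom_idx] - p, axis=1)
        if self.model.kind == "kernel":
            return self.model.kernel_weight * np.exp(-self.model.kernel_decay * d**2)
        return self._rad[atom_idx] - d

    def evaluate(self, p: np.ndarray) -> float:
        """f(p): positive inside the molecule, negative outside."""
        p = np.asarray(p, dtype=float)
        idx = self.grid.neighborhood(p)
        if self.model.kind == "kernel":
            # Gaussians beyond the 3x3x3 block contribute < weight*exp(-a*edge^2),
            # negligible by the grid sizing (3 sigma); sum the block only.
            total = float(np.sum(self._values_at(p, idx))) if idx.size else 0.0
            return total - self.model.kernel_threshold
        if idx.size:
            best = float(np.max(self._values_at(p, idx)))
            if best >= self.grid.out_of_block_bound:
                return best
        # neighborhood empty or not certifying the max: exact full scan
        return float(np.max(self._rad - np.linalg.norm(self._coords - p, axis=1)))

    def evaluate_many(self, points: np.ndarray) -> np.ndarray:
        """Vectorized f over an (n, 3) array of points.

        Points are grouped by voxel so each group shares one neighbor list;
        agrees exactly with :meth:`evaluate` point by point.
        """
        points = np.asarray(points, dtype=float)
        if points.ndim == 1:
            return np.array([self.evaluate(points)])
        n = len(points)
        out = np.empty(n)
        keys = np.floor((points - self.grid.origin) / self.grid.voxel_edge).astype(np.int64)
        order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
        sorted_keys = keys[order]
        cut = np.nonzero(np.any(np.diff(sorted_keys, axis=0) != 0, axis=1))[0] + 1
        for chunk in np.split(order, cut):
            pts = points[chunk]
            idx = self.grid.neighborhood(pts[0])
            if self.model.kind == "kernel":
                if idx.size:
                    d2 = np.sum(
                        (pts[:, None, :] - self._coords[idx][None, :, :]) ** 2, axis=2
                    )
                    dens = np.sum(
                        self.model.kernel_weight
                        * np.exp(-self.model.kernel_decay * d2),
                        axis=1,
                    )
                else:
                    dens = np.zeros(len(pts))
                out[chunk] = dens - self.model.kernel_threshold
                continue
            if idx.size:
                d = np.sqrt(
                    np.sum((pts[:, None, :] - self._coords[idx][None, :, :]) ** 2, axis=2)
                )
                best = np.max(self._rad[idx][None, :] - d, axis=1)
            else:
                best = np.full(len(pts), -np.inf)
            weak = best < self.grid.out_of_block_bound
            if np.any(weak):
                sub = pts[weak]
                d = np.sqrt(
                    np.sum((sub[:, None, :] - self._coords[None, :, :]) ** 2, axis=2)
                )
                best[weak] = np.max(self._rad[None, :] - d, axis=1)
            out[chunk] = best
        return out

    # -------------------------------------------------------------- gradient

    def _maximizer(self, p: np.ndarray) -> int:
        """Index of the atom realizing the max (ties -> lowest atom index)."""
        idx = self.grid.neighborhood(p)
        if idx.size:
            vals = self._values_at(p, idx)
            best = float(vals.max())
            if best >= self.grid.out_of_block_bound:
                return int(idx[int(np.argmax(vals))])  # idx sorted: argmax = lowest tie
        vals = self._rad - np.linalg.norm(self._coords - p, axis=1)
        return int(np.argmax(vals))

    def gradient(self, p: np.ndarray) -> tuple[np.ndarray, float]:
        """(unit gradient direction, magnitude) of f at p.

        For vdw/sas this is the gradient of the maximizing sphere term: a
        unit vector pointing toward that atom's center (f increases inward).
        A zero-magnitude gradient (p at the maximizing atom's center, or a
        kernel saddle) is reported as magnitude 0; callers perturb.
        """
        p = np.asarray(p, dtype=float)
        if self.model.kind == "kernel":
            idx = self.grid.neighborhood(p)
            if idx.size == 0:
                return np.zeros(3), 0.0
            diff = p - self._coords[idx]
            d2 = np.sum(diff**2, axis=1)
            w = (
                -2.0
                * self.model.kernel_decay
                * self.model.kernel_weight
                * np.exp(-self.model.kernel_decay * d2)
            )
            g = np.sum(w[:, None] * diff, axis=0)
            mag = float(np.linalg.norm(g))
            return (g / mag if mag > 0 else np.zeros(3)), mag
        i = self._maximizer(p)
        v = self._coords[i] - p
        d = float(np.linalg.norm(v))
        if d == 0.0:
            return np.zeros(3), 0.0
        return v / d, 1.0

    def distance_estimate(self, p: np.ndarray) -> float:
        """Newton-step distance estimate |f(p)| / |grad f(p)| (>= 0).

        Exact for a single vdw/sas sphere; a lower bound on the true
        distance for unions, hence safe as a sphere-tracing step. Falls
        back to a conservative EPS_MIN step on a degenerate gradient.
        """
        p = np.asarray(p, dtype=float)
        f = self.evaluate(p)
        _, mag = self.gradient(p)
        if mag == 0.0:
            return EPS_MIN
        return abs(f) / mag

    # ------------------------------------------------------------------ rays

    def trace_ray(
        self,
        origin: np.ndarray,
        direction: np.ndarray,
        max_len: Optional[float] = None,
    ) -> Optional[np.ndarray]:
        """Sphere-trace from an outside point until the surface is hit.

        Steps by max(distance_estimate, EPS_MIN) along ``direction`` (unit)
        while f < 0; on sign change the hit is refined by bisection to
        |f| < EPS_ISO. Returns the hit point, or None if the accumulated
        length exceeds ``max_len`` (default: frame bounding-box diagonal)
        or the step budget N_MAX runs out.
        """
        origin = np.asarray(origin, dtype=float)
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        if max_len is None:
            max_len = self.frame.bbox_diagonal + 2.0 * (
                self.grid.radius_max + self.grid.probe_max
            )

        f0 = self.evaluate(origin)
        if f0 >= 0:
            raise ValueError("trace_ray requires an outside origin (f < 0)")

        traveled = 0.0
        p = origin
        f = f0
        # For vdw/sas the Newton step is a true lower bound on the distance
        # to the surface; for the kernel field it is only an estimate (and
        # blows up where the gradient vanishes), so it is capped at the
        # Gaussian length scale 1/sqrt(a) — smaller than any region the
        # kernel density can push above the threshold.
        cap = (
            1.0 / np.sqrt(self.model.kernel_decay)
            if self.model.kind == "kernel"
            else np.inf
        )
        for _ in range(N_MAX):
            step = max(abs(f) / max(self.gradient(p)[1], 1e-12), EPS_MIN)
            step = min(step, cap)
            if traveled + step > max_len:
                return None
            q = p + step * direction
            fq = self.evaluate(q)
            if fq >= 0.0:
                return self._bisect(p, q)
            p, f = q, fq
            traveled += step
        logger.debug("trace_ray: step budget exhausted")
        return None

    def _bisect(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Refine a bracketed surface crossing to |f| < EPS_ISO."""
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            f = self.evaluate(mid)
            if abs(f) < EPS_ISO:
                return mid
            if f < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def evaluate_brute_force(model: SurfaceModel, frame: MolecularFrame, p: np.ndarray) -> float:
    """Reference f(p) scanning all atoms, no grid. Oracle for the grid path."""
    p = np.asarray(p, dtype=float)
    d = np.linalg.norm(frame.coords - p, axis=1)
    if model.kind == "kernel":
        dens = np.sum(model.kernel_weight * np.exp(-model.kernel_decay * d**2))
        return float(dens - model.kernel_threshold)
    return float(np.max(frame.radii + model.effective_probe - d))
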