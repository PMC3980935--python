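"""Stochastic cavity-sample detection.

Candidate points are seeded in a shell around every atom (k samples per
atom at radius r_i .. r_i + 2R from the center), which concentrates samples
where atoms — and therefore surface features — are dense. Samples inside
the molecule (f >= 0) are discarded. Each surviving sample is tested with a
single ray cast along the outward surface normal: if the ray re-hits the
surface, the sample lies between two opposite-facing surface patches and is
a cavity sample. Its position is then moved to the midpoint of the two
ray/surface intersections (the cavity midline) and its radius is the
distance from that midpoint to the surface.

The single-ray test deliberately misses shallow, open depressions: a cavity
here is a concave patch with at most a narrow mouth. Sampling is keyed by
(seed, atom index, sample index), so a fixed seed gives bit-identical
samples and, across trajectory frames, samples that ride along with their
atoms. A "fixed"-space mode instead keeps sample positions (relative to the
frame bounding box) constant over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .molecule_io import MolecularFrame
from .surface import SurfaceField

logger = logging.getLogger(__name__)


@dataclass
class CavitySample:
    """A confirmed cavity point: midline position, its two surface hits and
    the distance-to-surface radius."""

    position: np.ndarray
    source_atom: int
    near_hit: np.ndarray
    far_hit: np.ndarray
    radius: float


def seed_samples(
    frame: MolecularFrame,
    samples_per_atom: int = 16,
    seed: int = 0,
    probe_radius: float = 1.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Seed k random points in the shell [r_i, r_i + 2R] around each atom.

    Returns ``(positions, source_atoms)`` with exactly ``k * len(frame)``
    rows. The RNG is keyed by (seed, atom index), and sample j of an atom is
    the j-th draw of that stream, so the set is deterministic for a fixed
    seed and independent of every other atom. The shell width 2R is tied to
    the solvent probe: beyond it an atom cannot influence the SAS.
    """
    if samples_per_atom < 1:
        raise ValueError("samples_per_atom must be >= 1")
    k = int(samples_per_atom)
    n = len(frame)
    positions = np.empty((n * k, 3))
    source = np.repeat(np.arange(n), k)
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        direction = rng.normal(size=(k, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        u = rng.uniform(frame.radii[i], frame.radii[i] + 2.0 * probe_radius, size=k)
        positions[i * k:(i + 1) * k] = frame.coords[i] + u[:, None] * direction
    return positions, source


def reposition_fixed(
    positions: np.ndarray,
    reference_frame: MolecularFrame,
    frame: MolecularFrame,
) -> np.ndarray:
    """Map sample positions from the reference frame's bounding box to the
    current frame's (the fixed-space sampling variant): positions stay
    almost the same over time, adjusted affinely for bounding-box drift."""
    lo0, hi0 = reference_frame.bounds
    lo1, hi1 = frame.bounds
    scale = (hi1 - lo1) / np.where(hi0 - lo0 > 0, hi0 - lo0, 1.0)
    return lo1 + (positions - lo0) * scale


def filter_exterior(
    positions: np.ndarray,
    source_atoms: np.ndarray,
    field: SurfaceField,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep only samples outside the molecule (f < 0).

    By construction of the seeding shell every retained sample lies within
    2R of the surface.
    """
    f = field.evaluate_many(positions)
    keep = f < 0.0
    return positions[keep], source_atoms[keep]


def classify_cavity_samples(
    positions: np.ndarray,
    source_atoms: np.ndarray,
    field: SurfaceField,
    max_len: float | None = None,
) -> list[CavitySample]:
    """Single-ray cavity test with midline repositioning.

    For each exterior sample p the outward normal is -grad f / |grad f|.
    The ray toward the surface (against the normal) gives the near hit; the
    ray along the normal gives the far hit if an opposite-facing surface
    exists within ``max_len``. Samples with a far hit are cavity samples,
    repositioned to the midpoint of the two hits; their radius is the
    distance estimate there. Samples with a degenerate gradient, a missing
    near hit, or a midpoint that lands inside the molecule are dropped and
    counted in the log.
    """
    out: list[CavitySample] = []
    n_degenerate = n_no_near = n_bad_mid = 0
    for p, src in zip(positions, source_atoms):
        grad_dir, mag = field.gradient(p)
        if mag == 0.0:
            n_degenerate += 1
            continue
        outward = -grad_dir
        near = field.trace_ray(p, grad_dir, max_len=max_len)
        if near is None:  # cannot happen for vdw/sas; kernel saddles only
            n_no_near += 1
            continue
        far = field.trace_ray(p, outward, max_len=max_len)
        if far is None:
            continue  # open to the outside: not a cavity sample
        mid = 0.5 * (near + far)
        if field.evaluate(mid) >= 0.0:
            n_bad_mid += 1
            continue
        out.append(
            CavitySample(
                position=mid,
                source_atom=int(src),
                near_hit=near,
                far_hit=far,
                radius=field.distance_estimate(mid),
            )
        )
    if n_degenerate or n_no_near or n_bad_mid:
        logger.info(
            "classify_cavity_samples: dropped %d degenerate-gradient, "
            "%d no-near-hit, %d interior-midpoint samples",
            n_degenerate, n_no_near, n_bad_mid,
        )
    return out


def detect_cavity_samples(
    frame: MolecularFrame,
    field: SurfaceField,
    samples_per_atom: int = 16,
    seed: int = 0,
    max_len: float | None = None,
) -> list[CavitySample]:
    """Seed, filter and classify in one call (stages a-e of the pipeline)."""
    pos, src = seed_samples(
        frame, samples_per_atom, seed, probe_radius=field.model.probe_radius
    )
    pos, src = filter_exterior(pos, src, field)
    return classify_cavity_samples(pos, src, field, max_len=max_len)
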