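"""Shared fixtures: synthetic molecules, fields and one full detection run
per expensive fixture (session-scoped so the suite stays fast)."""

from __future__ import annotations

import numpy as np
import pytest

from cavigraph import fixtures as fx
from cavigraph.molecule_io import Atom, MolecularFrame
from cavigraph.pipeline import Config, detect_frame
from cavigraph.surface import SurfaceField, SurfaceModel


def make_frame(positions, res_nums=None, res_names=None, radius=1.7) -> MolecularFrame:
    """Build an ad-hoc frame of carbons (or custom labels) for geometry tests."""
    n = len(positions)
    res_nums = res_nums if res_nums is not None else [1] * n
    res_names = res_names if res_names is not None else ["GLY"] * n
    atoms = [
        Atom(i + 1, "C", rn_name, rn, "A",
             (float(p[0]), float(p[1]), float(p[2])), radius)
        for i, (p, rn, rn_name) in enumerate(zip(positions, res_nums, res_names))
    ]
    return MolecularFrame(atoms)


def make_parallel_plates(gap: float = 12.0, half: int = 5, spacing: float = 1.8):
    """Two facing square plates of carbons: the canonical slit cavity.

    With the SAS probe (inflated radius 3.1) the facing surfaces are the
    planes z = 3.1 and z = gap - 3.1; the slit midplane is z = gap / 2.
    """
    ax = np.arange(-half, half + 1) * spacing
    pos = [(x, y, z) for z in (0.0, gap) for x in ax for y in ax]
    return make_frame(pos)


@pytest.fixture(scope="session")
def lone_atom_field():
    frame, _ = fx.make_lone_atom()
    return SurfaceField(SurfaceModel(), frame)


@pytest.fixture(scope="session")
def slab_pocket():
    frame, gt = fx.make_slab_pocket()
    return frame, gt


@pytest.fixture(scope="session")
def slab_detection(slab_pocket):
    frame, gt = slab_pocket
    return detect_frame(frame, Config()), frame, gt


@pytest.fixture(scope="session")
def shell_detection():
    frame, gt = fx.make_hollow_shell()
    return detect_frame(frame, Config()), frame, gt


@pytest.fixture(scope="session")
def breathing_run():
    frames, gt = fx.make_breathing_trajectory()
    per_frame = {f.frame_index: detect_frame(f, Config()) for f in frames}
    return per_frame, frames, gt
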