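"""End-to-end per-frame cavity detection and corpus queries.

``run_detection`` executes, for every selected frame: spatial grid build ->
shell sampling -> exterior filter -> normal-ray cavity classification ->
visibility graph -> connected components -> MST skeletons -> graph
attributes -> residue assignment -> chemical profiles. Outputs are tabular
(cavities.csv), structural (GraphML / JSON per frame), an optional
pseudo-atom PDB per frame, and a run manifest recording the configuration
and seed. Every stage is a pure function of (frame, config, seed), so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .graphs import CavityGraph, build_components, write_graphml, write_json
from .molecule_io import (
    MolecularFrame,
    ResidueClassTable,
    read_pdb,
    read_trajectory,
    write_cavity_spheres,
)
from .query import (
    parse_query,
    presence_fraction,
    residue_occurrence_ranking,
    select,
)
from .residues import annotate_graphs
from .sampling import detect_cavity_samples
from .surface import SurfaceField, SurfaceModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Config:
    """Detection parameters (Angstrom units throughout).

    d_vis defaults to 2 * (2R) = 5.6: candidate visibility edges join
    samples within two probe diameters. d_g defaults to 3R. delta (segment
    probing step) defaults to R/2. ``sample_mode`` is "atom" (samples ride
    with their source atom across frames) or "fixed" (positions held in
    frame-0 bounding-box coordinates).
    """

    surface: str = "sas"
    probe_radius: float = 1.4
    samples_per_atom: int = 16
    seed: int = 0
    d_vis: Optional[float] = None
    d_g: Optional[float] = None
    n_min: int = 3
    delta: Optional[float] = None
    max_ray_len: Optional[float] = None
    attributes_on: str = "visibility"
    sample_mode: str = "atom"
    chain_qualified: bool = False
    residue_class_overrides: dict = field(default_factory=dict)

    def resolved(self) -> "Config":
        r = self.probe_radius
        return replace(
            self,
            d_vis=self.d_vis if self.d_vis is not None else 4.0 * r,
            d_g=self.d_g if self.d_g is not None else 3.0 * r,
            delta=self.delta if self.delta is not None else r / 2.0,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Read a plain key=value config file (# comments allowed)."""
        kwargs = {}
        casts = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # noqa: F841
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("surface", "attributes_on", "sample_mode"):
                kwargs[key] = value
            elif key in ("samples_per_atom", "seed", "n_min"):
                kwargs[key] = int(value)
            elif key == "chain_qualified":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in ("probe_radius", "d_vis", "d_g", "delta", "max_ray_len"):
                kwargs[key] = float(value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


def detect_frame(
    frame: MolecularFrame, config: Config
) -> list[CavityGraph]:
    """Run the full detection pipeline on one frame."""
    cfg = config.resolved()
    model = SurfaceModel(kind=cfg.surface, probe_radius=cfg.probe_radius)
    field_ = SurfaceField(model, frame)
    samples = detect_cavity_samples(
        frame,
        field_,
        samples_per_atom=cfg.samples_per_atom,
        seed=cfg.seed,
        max_len=cfg.max_ray_len,
    )
    graphs = build_components(
        samples,
        field_,
        frame_index=frame.frame_index,
        d_vis=cfg.d_vis,
        delta=cfg.delta,
        n_min=cfg.n_min,
        attributes_on=cfg.attributes_on,
    )
    table = ResidueClassTable()
    table.mapping.update(
        {k.upper(): v for k, v in cfg.residue_class_overrides.items()}
    )
    annotate_graphs(
        graphs, field_, frame,
        d_g=cfg.d_g, class_table=table, chain_qualified=cfg.chain_qualified,
    )
    logger.info(
        "frame %d: %d cavity samples -> %d components",
        frame.frame_index, len(samples), len(graphs),
    )
    return graphs


def graphs_to_table(per_frame: Mapping[int, Sequence[CavityGraph]]) -> pd.DataFrame:
    """One row per cavity graph across all frames."""
    rows = []
    for t in sorted(per_frame):
        for g in per_frame[t]:
            ratios = (g.profile or {}).get("ratios", {})
            rows.append(
                {
                    "frame": t,
                    "graph_id": g.graph_id,
                    "node_count": g.node_count,
                    "avg_path_length": round(g.avg_path_length, 6),
                    "diameter": round(g.diameter, 6),
                    "avg_degree": round(g.avg_degree, 6),
                    "hydrophobic": round(ratios.get("hydrophobic", 0.0), 6),
                    "polar": round(ratios.get("polar", 0.0), 6),
                    "positive": round(ratios.get("positive", 0.0), 6),
                    "negative": round(ratios.get("negative", 0.0), 6),
                    "residues": ";".join(
                        str(r) for r in sorted(g.residues or set())
                    ),
                }
            )
    columns = [
        "frame", "graph_id", "node_count", "avg_path_length", "diameter",
        "avg_degree", "hydrophobic", "polar", "positive", "negative",
        "residues",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_detection(
    topology: str | Path | Sequence[MolecularFrame],
    trajectory: str | Path | None = None,
    config: Config = Config(),
    outdir: str | Path | None = None,
    frames_spec: str | None = None,
    write_spheres: bool = False,
) -> dict[int, list[CavityGraph]]:
    """Detect cavities on every selected frame; optionally write a corpus.

    ``topology`` may be a PDB path (with optional DCD ``trajectory``) or an
    in-memory frame sequence. ``frames_spec`` is "start:stop:stride". With
    ``outdir``, writes cavities.csv, per-frame GraphML + JSON, a manifest,
    and (optionally) pseudo-atom sphere PDBs. Frames whose detection fails
    are logged and skipped; their indices appear in the manifest.
    """
    start = stop = stride = None
    if frames_spec:
        parts = (frames_spec.split(":") + ["", ""])[:3]
        start, stop, stride = (int(p) if p else None for p in parts)

    if isinstance(topology, (str, Path)):
        if trajectory is not None:
            frames = read_trajectory(
                topology, trajectory, start=start, stop=stop, stride=stride
            )
        else:
            frames = read_pdb(topology)[slice(start, stop, stride)]
    else:
        frames = list(topology)[slice(start, stop, stride)]

    per_frame: dict[int, list[CavityGraph]] = {}
    failed: list[int] = []
    for frame in frames:
        try:
            per_frame[frame.frame_index] = detect_frame(frame, config)
        except Exception:  # pragma: no cover - per-frame robustness
            logger.exception("frame %d failed; skipping", frame.frame_index)
            failed.append(frame.frame_index)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        graphs_to_table(per_frame).to_csv(outdir / "cavities.csv", index=False)
        for t, graphs in per_frame.items():
            write_json(graphs, outdir / f"graphs_frame{t:05d}.json")
            if graphs:
                write_graphml(graphs, outdir / f"graphs_frame{t:05d}.graphml")
            if write_spheres and graphs:
                write_cavity_spheres(graphs, outdir / f"spheres_frame{t:05d}.pdb")
        manifest = {
            "version": __version__,
            "config": asdict(config.resolved()),
            "n_frames": len(frames),
            "frame_indices": sorted(per_frame),
            "frames_failed": failed,
            "total_graphs": sum(len(g) for g in per_frame.values()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    if failed:
        logger.warning("%d frame(s) failed: %s", len(failed), failed)
    return per_frame


def load_corpus(outdir: str | Path) -> dict[int, list[tuple[int, set[int]]]]:
    """Reload a detection corpus (frame -> [(graph_id, residue set)]) from a
    directory written by :func:`run_detection`.

    Frames without cavities matter for temporal statistics, so the full
    frame list comes from the manifest, not just the CSV rows.
    """
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "cavities.csv", dtype={"residues": str})
    corpus: dict[int, list[tuple[int, set[int]]]] = {}
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        corpus = {int(t): [] for t in manifest.get("frame_indices", [])}
    for _, row in df.iterrows():
        cell = row["residues"]
        residues = (
            {int(x) for x in str(cell).split(";")}
            if isinstance(cell, str) and cell and cell != "nan"
            else set()
        )
        corpus.setdefault(int(row["frame"]), []).append(
            (int(row["graph_id"]), residues)
        )
    return corpus


def run_query(
    corpus: str | Path | Mapping,
    query_text: str | None = None,
    mode: str = "select",
):
    """Query a stored or in-memory corpus.

    mode="select" -> sorted (frame, graph_id) pairs; "fraction" -> presence
    fraction of the query over frames; "rank" -> residue occurrence ranking
    (query not required).
    """
    if isinstance(corpus, (str, Path)):
        corpus = load_corpus(corpus)
    if mode == "rank":
        return residue_occurrence_ranking(corpus)
    if query_text is None:
        raise ValueError(f"mode {mode!r} requires a query")
    q = parse_query(query_text)
    if mode == "select":
        return sorted(select(q, corpus))
    if mode == "fraction":
        return presence_fraction(q, corpus)
    raise ValueError(f"unknown mode {mode!r}")
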