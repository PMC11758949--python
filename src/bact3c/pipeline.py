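"""End-to-end pipeline orchestration with a flat YAML config and manifest.

Stages: read -> filter -> SCN normalize -> DI/CID calling -> distance decay
and significant contacts -> scalogram -> optional 3D embedding and metrics.
Each produced file is recorded in a manifest with a SHA-256 checksum so a
rerun with the same config and seeds can be verified bit-for-bit for the
deterministic stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    ContactMatrix,
    RepliconLayout,
    ValidationError,
    bin_genome,
    call_boundaries,
    call_significant,
    directionality_index,
    embed_structure,
    filter_bins,
    ps_curve,
    radius_of_gyration,
    read_contacts,
    scalogram,
    scn_normalize,
    write_contacts,
)

log = logging.getLogger("bact3c")


@dataclass
class PipelineConfig:
    layout_path: str
    matrix_path: str
    matrix_format: str = "triplet"
    bin_size_bp: int = 5_000
    min_coverage_quantile: float = 0.02
    scn_norm: str = "euclidean"
    scn_tol: float = 1e-6
    di_scale_bp: int = 100_000
    min_run_bins: int = 3
    di_quantile: float = 0.60
    alpha: float = 0.05
    min_count: int = 2
    embed: bool = False
    embed_alpha: float = 1.0
    seed: int = 0
    out_dir: str = "bact3c_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        for p, what in ((cfg.layout_path, "layout_path"), (cfg.matrix_path, "matrix_path")):
            if not Path(p).exists():
                raise ValidationError(f"{what} does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": vars(config).copy(), "stages": [], "files": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["files"][p.name] = _sha256(p)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    stage = "read"
    try:
        layout = RepliconLayout.from_yaml(config.layout_path)
        bins = bin_genome(layout, config.bin_size_bp)
        raw = read_contacts(config.matrix_path, config.matrix_format, bins)
        log.info("read %d x %d matrix (%s)", raw.n_bins, raw.n_bins, config.matrix_path)
        record(stage)

        stage = "normalize"
        mask = filter_bins(raw, config.min_coverage_quantile)
        res = scn_normalize(raw, norm=config.scn_norm, tol=config.scn_tol, mask=mask)
        norm_path = out / "normalized.tsv"
        write_contacts(res.matrix, norm_path, fmt="dense")
        (out / "normalize_log.json").write_text(json.dumps(
            {"n_iter": res.n_iter, "residual": res.residual, "converged": res.converged,
             "n_masked": int((~mask).sum()), "seed": config.seed}))
        record(stage, norm_path, out / "normalize_log.json")

        stage = "domains"
        di_rows, b_rows, c_rows = [], [], []
        for rep in layout.names:
            n_rep = bins.n_replicon_bins(rep)
            if n_rep * config.bin_size_bp <= 2 * config.di_scale_bp:
                log.info("skipping DI on %s (too small for scale)", rep)
                continue
            di = directionality_index(res.matrix, rep, config.di_scale_bp)
            s = bins.replicon_slice(rep)
            for k in range(di.di.size):
                di_rows.append((rep, k * config.bin_size_bp, (k + 1) * config.bin_size_bp,
                                di.di[k]))
            bset, cset = call_boundaries(di, bins, config.min_run_bins,
                                         di_quantile=config.di_quantile)
            for a, bb in bset.intervals:
                b_rows.append((rep, a * config.bin_size_bp, (bb + 1) * config.bin_size_bp))
            for a, bb in cset.segments:
                c_rows.append((rep, a * config.bin_size_bp, bb * config.bin_size_bp))
        di_path = out / "di.bedgraph"
        pd.DataFrame(di_rows).to_csv(di_path, sep="\t", header=False, index=False)
        b_path = out / "boundaries.bed"
        pd.DataFrame(b_rows).to_csv(b_path, sep="\t", header=False, index=False)
        c_path = out / "cids.bed"
        pd.DataFrame(c_rows).to_csv(c_path, sep="\t", header=False, index=False)
        record(stage, di_path, b_path, c_path)

        stage = "decay"
        curves = []
        for rep in layout.names:
            c = ps_curve(raw, rep, log_binning=True)
            c.table.insert(0, "replicon", rep)
            curves.append(c.table)
        ps_path = out / "ps_curve.tsv"
        pd.concat(curves).to_csv(ps_path, sep="\t", index=False)
        sig = call_significant(raw, layout.names[0], alpha=config.alpha,
                               min_count=config.min_count)
        sig_path = out / "significant.tsv"
        sig.to_csv(sig_path, sep="\t", index=False)
        record(stage, ps_path, sig_path)

        stage = "views"
        sc = scalogram(res.matrix, layout.names[0])
        sc_path = out / "scalogram.tsv"
        sc.to_frame().to_csv(sc_path, sep="\t", index=False)
        record(stage, sc_path)

        if config.embed:
            stage = "structure"
            model = embed_structure(res.matrix, alpha=config.embed_alpha)
            coords_path = out / "structure.tsv"
            model.to_table(coords_path)
            (out / "structure_metrics.json").write_text(json.dumps(
                {"rg": radius_of_gyration(model), "n_points": model.n_points}))
            record(stage, coords_path, out / "structure_metrics.json")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["status"] = "complete"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
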