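"""End-to-end workflows: atlas building, segmentation, delineation bootstrap.

Thin orchestration over the library modules, driven by a YAML/JSON config.
All randomness flows from a single top-level seed; artifact directories
carry a manifest (config hash, per-stage wall time) so a run is
reproducible from its manifest alone.  Pipeline NIfTI outputs are written
uncompressed so reruns are bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import evalseg, labelfuse, probatlas, template
from .register import RegConfig
from .volio import (
    LabelMap,
    RegionTable,
    read_labelmap,
    read_volume,
    write_labelmap,
    write_volume,
)

log = logging.getLogger("popatlas")

__all__ = ["load_config", "run_build", "run_segment", "run_bootstrap"]


def load_config(config) -> dict:
    """Accept a dict, or a path to a YAML/JSON config file."""
    if isinstance(config, dict):
        return config
    path = Path(config)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _reg_config(cfg: dict) -> RegConfig:
    return RegConfig(**cfg.get("registration", {}))


class _StageTimer:
    def __init__(self):
        self.stages = []

    def run(self, name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        out = fn(*args, **kwargs)
        dt = time.perf_counter() - t0
        log.info("stage %s: done in %.1f s", name, dt)
        self.stages.append({"stage": name, "seconds": round(dt, 3)})
        return out


def _load_subjects(cfg: dict):
    subjects = cfg.get("subjects")
    if not subjects:
        raise ValueError("config must list 'subjects'")
    regions_path = cfg.get("regions")
    if regions_path is None:
        raise ValueError("config must name a 'regions' TSV")
    regions = RegionTable.from_tsv(regions_path)
    volumes, labelmaps = [], []
    for i, entry in enumerate(subjects):
        if "t1" not in entry:
            raise ValueError(f"subject {i}: missing 't1' volume path")
        if "labels" not in entry:
            raise ValueError(f"subject {i} ({entry.get('t1')}): missing label map")
        t1_path, lab_path = Path(entry["t1"]), Path(entry["labels"])
        for p in (t1_path, lab_path):
            if not p.exists():
                raise FileNotFoundError(f"subject {i}: {p}")
        volumes.append(read_volume(t1_path))
        labelmaps.append(read_labelmap(lab_path, regions))
    return volumes, labelmaps, regions


def run_build(config, out_dir) -> Path:
    """Build template + probabilistic atlas from labeled subjects.

    Writes ``template.nii``, ``probabilities.nii``, per-subject fields,
    ``regions.tsv`` and ``manifest.json`` into ``out_dir``.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, out)
    volumes, labelmaps, _regions = _load_subjects(cfg)  # validate before compute
    reg_cfg = _reg_config(cfg)
    tpl_cfg = cfg.get("template", {})
    ref_over = tpl_cfg.get("reference_registration")
    ref_cfg = RegConfig(**ref_over) if ref_over else None
    timer = _StageTimer()
    tm = timer.run(
        "build_template",
        template.build_template,
        volumes,
        reg_cfg,
        tol=float(tpl_cfg.get("tol", 0.1)),
        max_iter=int(tpl_cfg.get("max_iter", 10)),
        ref_cfg=ref_cfg,
    )
    atlas = timer.run("probability_maps", probatlas.build_probability_maps, tm, labelmaps)
    probatlas.save_atlas(atlas, out)
    import nibabel as nib

    for i, f in enumerate(tm.subject_fields):
        img = nib.Nifti1Image(f.vectors.astype(np.float32), np.eye(4))
        nib.save(img, str(out / f"subject_{i:02d}_field.nii"))
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.get("seed"),
        "n_subjects": len(volumes),
        "template_iterations": tm.iterations_run,
        "template_converged": bool(tm.converged),
        "template_history": [float(h) for h in tm.history],
        "stages": timer.stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def run_segment(atlas_dir, volume_path, out_dir, reference_labels=None, config=None) -> Path:
    """Parcellate a new volume with a built atlas.

    With ``reference_labels`` (path or LabelMap) an evaluation block —
    per-region Dice, global index and a confusion TSV — is written too.
    """
    cfg = load_config(config) if config else {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, out)
    atlas = probatlas.load_atlas(atlas_dir)
    vol = read_volume(volume_path) if not hasattr(volume_path, "data") else volume_path
    if vol.shape != atlas.template.shape:
        raise ValueError(
            f"volume grid {vol.shape} incompatible with atlas {atlas.template.shape}"
        )
    timer = _StageTimer()
    labels, maxprob = timer.run("segment", probatlas.segment, vol, atlas, _reg_config(cfg))
    write_labelmap(labels, out / "segmentation.nii")
    write_volume(maxprob, out / "maxprob.nii")
    manifest = {"config_hash": _config_hash(cfg), "stages": timer.stages}
    if reference_labels is not None:
        ref = (
            reference_labels
            if isinstance(reference_labels, LabelMap)
            else read_labelmap(reference_labels, atlas.regions)
        )
        report = evalseg.evaluate(ref, labels)
        report.save(out / "report.json", out / "confusion.tsv")
        manifest["global_index"] = float(report.global_index)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def run_bootstrap(config, out_dir) -> Path:
    """Sequential delineation bootstrap.

    Starting from >= 1 labeled subject, each unlabeled subject (in config
    order) receives an initial parcellation by propagation + majority vote;
    the result (optionally replaced by supplied 'truth' labels, standing in
    for expert correction) joins the prior pool for the next subject.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, out)
    regions = RegionTable.from_tsv(cfg["regions"])
    labeled = cfg.get("labeled", [])
    unlabeled = cfg.get("unlabeled", [])
    if not labeled:
        raise ValueError("bootstrap needs at least one labeled seed subject")
    pool = [
        (read_volume(e["t1"]), read_labelmap(e["labels"], regions)) for e in labeled
    ]
    reg_cfg = _reg_config(cfg)
    affine_first = bool(cfg.get("affine_first", True))
    timer = _StageTimer()
    order = []
    for i, entry in enumerate(unlabeled):
        vol = read_volume(entry["t1"])
        init = timer.run(
            f"bootstrap_{i:02d}",
            labelfuse.bootstrap_initialization,
            vol,
            pool,
            reg_cfg,
            affine_first,
        )
        write_labelmap(init, out / f"bootstrap_{i:02d}_labels.nii")
        corrected = init
        if entry.get("truth"):  # oracle correction hook (synthetic expert)
            corrected = read_labelmap(entry["truth"], regions)
        pool.append((vol, corrected))
        order.append({"index": i, "t1": str(entry["t1"]), "pool_size": len(pool)})
    manifest = {
        "config_hash": _config_hash(cfg),
        "order": order,
        "stages": timer.stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _setup_logging(cfg: dict, out: Path):
    level = getattr(logging, str(cfg.get("log_level", "INFO")).upper(), logging.INFO)
    log.setLevel(level)
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(out / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
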