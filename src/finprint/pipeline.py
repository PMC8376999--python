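"""End-to-end orchestration: simulate -> extract-roi -> detect -> identify.

Each stage reads its inputs from, and writes its artifacts into, one
working directory, so stages can be run individually (also via the
command line) or chained with :func:`run_pipeline`.  Every run logs the
configuration hash and the matching parameters actually in effect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import detection, matching, roi as roi_mod, synthetic
from .cnn import PatchCNN
from .evaluation import identification_accuracy
from .hog import HOGConfig, identify_hog
from .io import (load_gallery, patterns_from_csv, patterns_to_csv,
                 results_to_csv, save_gallery)
from .types import NormalizedROI

log = logging.getLogger("finprint")

STAGES = ("simulate", "extract-roi", "train-detector", "detect", "enroll",
          "identify", "evaluate")


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML losslessly."""

    workdir: str = "finprint_run"
    seed: int = 0
    # simulation
    n_fish: int = 10
    images_per_fish: int = 3
    mode: str = "short"             # short | long
    n_sessions: int = 4
    dot_jitter_sd: float = 4.5      # between sessions (long mode)
    image_jitter_sd: float = 3.0    # between images of one fish
    n_dots_range: tuple = (8, 30)
    # detection
    detector: str = "blob"          # blob | cnn
    n_patches_per_class: int = 535
    scan_step: int = 5
    p_min: float = 0.30
    cluster_cutoff: float = 15.0
    # matching
    matcher: str = "dot"            # dot | hog
    n_templates: int = 2
    max_shift_short: float = 30.0
    max_shift_long: float = 50.0
    shift_step: float = 5.0
    trim_fraction: float = 0.75
    count_ratio_max: float = 2.0
    # segmentation
    hue_min: float = 90.0
    hue_max: float = 150.0
    sat_min: float = 0.30

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["n_dots_range"] = tuple(data.get("n_dots_range", (8, 30)))
        return cls(**data)

    # derived helpers -----------------------------------------------------
    def match_config(self, long_term: bool = False) -> matching.MatchConfig:
        return matching.MatchConfig(
            max_shift=self.max_shift_long if long_term else self.max_shift_short,
            shift_step=self.shift_step, trim_fraction=self.trim_fraction,
            count_ratio_max=self.count_ratio_max)

    def roi_config(self) -> roi_mod.ROIConfig:
        return roi_mod.ROIConfig(hue_min=self.hue_min, hue_max=self.hue_max,
                                 sat_min=self.sat_min)


def _wd(cfg: PipelineConfig) -> Path:
    wd = Path(cfg.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    return wd


def stage_simulate(cfg: PipelineConfig) -> Path:
    wd = _wd(cfg)
    if cfg.mode == "long":
        sessions = synthetic.long_term_sessions(
            cfg.n_sessions, dot_jitter_sd=cfg.dot_jitter_sd)
    else:
        sessions = [synthetic.SceneParams(session="SS")]
    cohort = synthetic.generate_cohort(
        cfg.n_fish, cfg.images_per_fish, sessions=sessions, seed=cfg.seed,
        n_dots_range=tuple(cfg.n_dots_range),
        image_jitter_sd=cfg.image_jitter_sd)
    manifest = cohort.save(wd / "images")
    log.info("simulate: %d images -> %s", len(cohort), manifest)
    return manifest


def stage_extract_roi(cfg: PipelineConfig) -> Path:
    wd = _wd(cfg)
    manifest = wd / "images" / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(
            "extract-roi: missing images/manifest.csv; run `simulate` first")
    df = pd.read_csv(manifest)
    roi_dir = wd / "rois"
    roi_dir.mkdir(exist_ok=True)
    rows = []
    rcfg = cfg.roi_config()
    for rec in df.itertuples():
        img = iio.imread(wd / "images" / rec.image_path)
        nroi, _obj = roi_mod.extract_normalized_roi(img, rcfg)
        out = roi_dir / f"{rec.image_id}_roi.png"
        iio.imwrite(out, np.clip(nroi.image, 0, 255).astype(np.uint8))
        (roi_dir / f"{rec.image_id}_landmarks.json").write_text(
            json.dumps(nroi.landmarks.as_dict()))
        rows.append({"roi_path": out.name, "image_id": rec.image_id,
                     "fish_id": rec.fish_id, "session": rec.session})
    out_manifest = roi_dir / "roi_manifest.csv"
    pd.DataFrame(rows).to_csv(out_manifest, index=False)
    log.info("extract-roi: %d ROIs", len(rows))
    return out_manifest


def stage_train_detector(cfg: PipelineConfig) -> Path:
    wd = _wd(cfg)
    ds = synthetic.generate_patches(cfg.n_patches_per_class, seed=cfg.seed + 3)
    clf, acc = detection.train_patch_classifier(ds, seed=cfg.seed)
    model = wd / "detector.npz"
    clf.save(model)
    (wd / "detector_meta.json").write_text(json.dumps(
        {"test_accuracy": acc, "n_per_class": cfg.n_patches_per_class,
         "seed": cfg.seed, "config_hash": cfg.hash()}))
    log.info("train-detector: held-out accuracy %.4f", acc)
    return model


def _load_rois(cfg: PipelineConfig) -> list[dict]:
    wd = _wd(cfg)
    manifest = wd / "rois" / "roi_manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(
            "missing rois/roi_manifest.csv; run `extract-roi` first")
    df = pd.read_csv(manifest)
    out = []
    for rec in df.itertuples():
        img = iio.imread(wd / "rois" / rec.roi_path).astype(float)
        out.append({"roi": NormalizedROI(image=img), "image_id": rec.image_id,
                    "fish_id": int(rec.fish_id), "session": rec.session})
    return out


def stage_detect(cfg: PipelineConfig) -> Path:
    wd = _wd(cfg)
    rois = _load_rois(cfg)
    if cfg.detector == "cnn":
        model = wd / "detector.npz"
        if not model.exists():
            raise FileNotFoundError(
                "detect: missing detector.npz; run `train-detector` first")
        clf = PatchCNN.load(model)

        def run(r):
            return detection.detect_dots(
                r["roi"], clf, step=cfg.scan_step, p_min=cfg.p_min,
                cluster_cutoff=cfg.cluster_cutoff)
    else:
        def run(r):
            return detection.detect_dots_blob(
                r["roi"], cluster_cutoff=cfg.cluster_cutoff)

    patterns = []
    for r in rois:
        pat = run(r)
        pat.image_id, pat.fish_id, pat.session = (
            r["image_id"], r["fish_id"], r["session"])
        patterns.append(pat)
    out = wd / "patterns.csv"
    patterns_to_csv(patterns, out)
    log.info("detect (%s): %d patterns, parameters step=%d p_min=%.2f "
             "cutoff=%.0f", cfg.detector, len(patterns), cfg.scan_step,
             cfg.p_min, cfg.cluster_cutoff)
    return out


def stage_enroll(cfg: PipelineConfig) -> list[Path]:
    wd = _wd(cfg)
    pats_file = wd / "patterns.csv"
    if not pats_file.exists():
        raise FileNotFoundError("enroll: missing patterns.csv; run `detect`")
    patterns = patterns_from_csv(pats_file)
    outs = []
    if cfg.mode == "short":
        gallery: dict = {}
        template_ids: list[str] = []
        by_fish: dict = {}
        for p in sorted(patterns, key=lambda p: p.image_id):
            by_fish.setdefault(p.fish_id, []).append(p)
        for fid, pats in by_fish.items():
            gallery[fid] = pats[: cfg.n_templates]
            template_ids += [p.image_id for p in gallery[fid]]
        out = wd / "gallery.json"
        save_gallery(gallery, out, template_ids)
        outs.append(out)
    else:
        sessions = sorted({p.session for p in patterns})
        mc = cfg.match_config(long_term=False)
        for sess in sessions:
            gallery = {}
            by_fish = {}
            for p in patterns:
                if p.session == sess:
                    by_fish.setdefault(p.fish_id, []).append(p)
            for fid, pats in by_fish.items():
                gallery[fid] = matching.build_representative(
                    sorted(pats, key=lambda p: p.image_id), mc,
                    fish_id=fid, session=sess)
            out = wd / f"gallery_{sess}.json"
            save_gallery(gallery, out)
            outs.append(out)
    log.info("enroll (%s): %s", cfg.mode, [o.name for o in outs])
    return outs


def _identify_hog(cfg: PipelineConfig) -> list:
    """HOG-matcher identification straight from the stored ROIs."""
    rois = _load_rois(cfg)
    hcfg = HOGConfig()
    by_key: dict = {}
    for r in sorted(rois, key=lambda r: r["image_id"]):
        by_key.setdefault((r["session"], r["fish_id"]), []).append(r)
    results = []
    if cfg.mode == "short":
        gallery = {fid: [e["roi"] for e in entries[: cfg.n_templates]]
                   for (_s, fid), entries in by_key.items()}
        for (sess, fid), entries in sorted(by_key.items()):
            for e in entries[cfg.n_templates:]:
                res = identify_hog(e["roi"], gallery, hcfg,
                                   query_id=e["image_id"], true_id=fid)
                res.session_pair = (sess, sess)
                results.append(res)
    else:
        sessions = sorted({s for s, _f in by_key})
        for gal_sess in sessions:
            gallery = {fid: [e["roi"] for e in entries]
                       for (s, fid), entries in by_key.items() if s == gal_sess}
            for q_sess in sessions:
                if q_sess == gal_sess:
                    continue
                for (s, fid), entries in sorted(by_key.items()):
                    if s != q_sess:
                        continue
                    res = identify_hog([e["roi"] for e in entries], gallery,
                                       hcfg, query_id=f"f{fid}_{q_sess}",
                                       true_id=fid)
                    res.session_pair = (gal_sess, q_sess)
                    results.append(res)
    return results


def stage_identify(cfg: PipelineConfig) -> Path:
    wd = _wd(cfg)
    if cfg.matcher == "hog":
        results = _identify_hog(cfg)
        out = wd / "results.csv"
        results_to_csv(results, out)
        log.info("identify (hog): %d queries", len(results))
        return out
    patterns = patterns_from_csv(wd / "patterns.csv")
    results = []
    if cfg.mode == "short":
        gfile = wd / "gallery.json"
        if not gfile.exists():
            raise FileNotFoundError("identify: missing gallery.json; run `enroll`")
        gallery, template_ids = load_gallery(gfile)
        mc = cfg.match_config(long_term=False)
        log.info("identify: shift grid +/-%.0f step %.0f, trim %.2f",
                 mc.max_shift, mc.shift_step, mc.trim_fraction)
        for p in patterns:
            if p.image_id in template_ids:
                continue
            results.append(matching.identify_short_term(p, gallery, mc))
    else:
        sessions = sorted({p.session for p in patterns})
        galleries = {}
        for sess in sessions:
            gfile = wd / f"gallery_{sess}.json"
            if not gfile.exists():
                raise FileNotFoundError(
                    f"identify: missing gallery_{sess}.json; run `enroll`")
            galleries[sess], _ = load_gallery(gfile)
        mc = cfg.match_config(long_term=True)
        for gal_sess in sessions:
            for q_sess in sessions:
                if gal_sess == q_sess:
                    continue
                for fid, rep in sorted(galleries[q_sess].items()):
                    r = matching.identify_long_term(
                        rep, galleries[gal_sess], mc,
                        session_pair=(gal_sess, q_sess))
                    results.append(r)
    out = wd / "results.csv"
    results_to_csv(results, out)
    log.info("identify: %d queries", len(results))
    return out


def stage_evaluate(cfg: PipelineConfig) -> Path:
    wd = _wd(cfg)
    rfile = wd / "results.csv"
    if not rfile.exists():
        raise FileNotFoundError("evaluate: missing results.csv; run `identify`")
    df = pd.read_csv(rfile)
    from .types import MatchResult
    results = [
        MatchResult(query_id=str(r.query_id), true_id=int(r.true_id),
                    predicted_id=int(r.predicted_id),
                    distances={int(r.predicted_id): r.distance},
                    best_shifts={}, session_pair=(str(r.gallery_session),
                                                  str(r.query_session)))
        for r in df.itertuples()]
    report = identification_accuracy(results, matcher=cfg.matcher)
    out = wd / "report.json"
    out.write_text(json.dumps({
        "matcher": cfg.matcher, "config_hash": cfg.hash(),
        "overall_accuracy": report.overall,
        "per_pair": {f"{g}->{q}": round(a, 1)
                     for (g, q), a in report.per_pair.items()},
        "counts": {f"{g}->{q}": list(c)
                   for (g, q), c in report.counts.items()}}))
    report.to_frame().to_csv(wd / "report_matrix.csv")
    log.info("evaluate: overall %.1f%%", report.overall)
    return out


_STAGE_FN = {
    "simulate": stage_simulate,
    "extract-roi": stage_extract_roi,
    "train-detector": stage_train_detector,
    "detect": stage_detect,
    "enroll": stage_enroll,
    "identify": stage_identify,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in canonical order; returns artifact paths."""
    chosen = list(STAGES) if stages is None else list(stages)
    if cfg.detector != "cnn" and stages is None:
        chosen.remove("train-detector")
    unknown = set(chosen) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    log.info("run %s: stages %s (config %s)", cfg.workdir, chosen, cfg.hash())
    artifacts = {}
    for name in STAGES:
        if name in chosen:
            artifacts[name] = _STAGE_FN[name](cfg)
    return artifacts
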