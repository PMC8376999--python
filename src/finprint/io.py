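"""Plain-text serialization: pattern CSVs, gallery JSON, result CSVs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import DotPattern, MatchResult, RepresentativePattern


def patterns_to_csv(patterns: Sequence[DotPattern], path: str | Path) -> None:
    rows = []
    for p in patterns:
        for x, y in p.points:
            rows.append({"image_id": p.image_id, "fish_id": p.fish_id,
                         "session": p.session, "x": x, "y": y})
    pd.DataFrame(rows, columns=["image_id", "fish_id", "session", "x", "y"]
                 ).to_csv(path, index=False, float_format="%.3f")


def patterns_from_csv(path: str | Path) -> list[DotPattern]:
    df = pd.read_csv(path)
    out = []
    for image_id, g in df.groupby("image_id", sort=True):
        fid = g["fish_id"].iloc[0]
        out.append(DotPattern(
            points=g[["x", "y"]].to_numpy(float),
            image_id=str(image_id),
            fish_id=None if pd.isna(fid) else int(fid),
            session=str(g["session"].iloc[0])))
    return out


def save_gallery(gallery: Mapping, path: str | Path,
                 template_ids: Sequence[str] = ()) -> None:
    """Gallery JSON: fish id -> templates (dot patterns or representatives)."""
    blob: dict = {"template_image_ids": list(template_ids), "fish": {}}
    for fid, entry in gallery.items():
        if isinstance(entry, RepresentativePattern):
            blob["fish"][str(fid)] = {
                "kind": "representative", "session": entry.session,
                "points": entry.points.tolist(),
                "support": entry.support.tolist(),
                "n_source_patterns": entry.n_source_patterns}
        else:
            pats = entry if isinstance(entry, (list, tuple)) else [entry]
            blob["fish"][str(fid)] = {
                "kind": "templates",
                "templates": [{"image_id": p.image_id, "session": p.session,
                               "points": p.points.tolist()} for p in pats]}
    Path(path).write_text(json.dumps(blob))


def load_gallery(path: str | Path) -> tuple[dict, list[str]]:
    blob = json.loads(Path(path).read_text())
    gallery: dict = {}
    for fid_s, entry in blob["fish"].items():
        fid = int(fid_s)
        if entry["kind"] == "representative":
            gallery[fid] = RepresentativePattern(
                points=np.asarray(entry["points"], float),
                support=np.asarray(entry["support"], int),
                n_source_patterns=entry["n_source_patterns"],
                fish_id=fid, session=entry["session"])
        else:
            gallery[fid] = [DotPattern(np.asarray(t["points"], float),
                                       image_id=t["image_id"], fish_id=fid,
                                       session=t["session"])
                            for t in entry["templates"]]
    return gallery, list(blob.get("template_image_ids", []))


def results_to_csv(results: Sequence[MatchResult], path: str | Path) -> None:
    rows = []
    for r in results:
        dx, dy = r.best_shifts.get(r.predicted_id, (np.nan, np.nan))
        rows.append({
            "query_id": r.query_id, "true_id": r.true_id,
            "predicted_id": r.predicted_id,
            "distance": r.distances.get(r.predicted_id, np.nan),
            "dx": dx, "dy": dy,
            "gallery_session": r.session_pair[0],
            "query_session": r.session_pair[1]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.3f")
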