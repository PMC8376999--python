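"""Accuracy bookkeeping and pattern-stability analysis.

``identification_accuracy`` turns match results into the per-session-pair
accuracy matrix used to report closed-set identification performance.
``align_similarity`` / ``displacement_analysis`` implement the manual
pattern-validation protocol: corresponding dots labeled across sessions
are aligned with a least-squares similarity transform (shift, rotation,
scale) per fish, and the residual per-axis displacements quantify how
stable the skin pattern is over months of growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import SimilarityTransform

from .types import MatchResult


@dataclass
class AccuracyReport:
    """Identification accuracy per session pair, Table-style."""

    per_pair: dict            # (gallery_session, query_session) -> accuracy %
    counts: dict              # pair -> (n_correct, n_total)
    matcher: str = ""
    confusion: dict = field(default_factory=dict)  # pair -> list[(true, pred)]

    @property
    def overall(self) -> float:
        c = sum(v[0] for v in self.counts.values())
        n = sum(v[1] for v in self.counts.values())
        return 100.0 * c / n if n else float("nan")

    @property
    def minimum(self) -> float:
        return min(self.per_pair.values())

    def to_frame(self) -> pd.DataFrame:
        """Session-pair matrix with accuracies rounded to one decimal."""
        sessions = sorted({s for pair in self.per_pair for s in pair})
        df = pd.DataFrame(index=sessions, columns=sessions, dtype=float)
        for (ga, qu), acc in self.per_pair.items():
            df.loc[ga, qu] = round(acc, 1)
        return df


def identification_accuracy(
    results: Sequence[MatchResult], matcher: str = "dot"
) -> AccuracyReport:
    """Exact fraction correct per session pair.

    Every result must carry ground truth; accuracy is permutation
    invariant in the query order.
    """
    per_pair_counts: dict = {}
    confusion: dict = {}
    for r in results:
        if r.true_id is None:
            raise ValueError(f"query {r.query_id} has no ground truth")
        pair = tuple(r.session_pair)
        c, n = per_pair_counts.get(pair, (0, 0))
        per_pair_counts[pair] = (c + int(r.correct), n + 1)
        confusion.setdefault(pair, []).append((r.true_id, r.predicted_id))
    per_pair = {p: 100.0 * c / n for p, (c, n) in per_pair_counts.items()}
    return AccuracyReport(per_pair=per_pair, counts=per_pair_counts,
                          matcher=matcher, confusion=confusion)


def align_similarity(
    points_a: np.ndarray, points_b: np.ndarray
) -> tuple[float, float, tuple[float, float], np.ndarray]:
    """Least-squares similarity transform taking b onto a.

    Points correspond by index.  Returns (scale, rotation_deg,
    (tx, ty), residual vectors a - T(b)); the closed-form (Umeyama)
    solution minimizes the sum of squared residuals.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 corresponding point pairs")
    if np.allclose(b, b[0]) or np.allclose(a, a[0]):
        raise ValueError("degenerate alignment: coincident points")
    if hasattr(SimilarityTransform, "from_estimate"):
        tf = SimilarityTransform.from_estimate(b, a)
        if not tf:
            raise ValueError("similarity estimation failed")
    else:  # older scikit-image
        tf = SimilarityTransform()
        if not tf.estimate(b, a):
            raise ValueError("similarity estimation failed")
    residuals = a - tf(b)
    return (float(tf.scale), float(np.degrees(tf.rotation)),
            (float(tf.translation[0]), float(tf.translation[1])), residuals)


def displacement_analysis(
    series: Mapping[str, np.ndarray] | Sequence[np.ndarray]
) -> tuple[float, float]:
    """Mean per-axis dot displacement across sessions after alignment.

    ``series`` holds, per session, the same K labeled dot positions of
    one fish (correspondence by index; the first entry is the reference
    session).  Each later session is similarity-aligned to the first;
    the result is the mean |dx| and |dy| of the aligned dots relative to
    their reference positions, averaged over dots and sessions.
    """
    if isinstance(series, Mapping):
        keys = sorted(series)
        sets = [np.asarray(series[k], dtype=float) for k in keys]
    else:
        sets = [np.asarray(s, dtype=float) for s in series]
    if len(sets) < 2:
        raise ValueError("need at least two sessions")
    k = len(sets[0])
    if any(len(s) != k for s in sets):
        raise ValueError("sessions must label the same number of dots")
    ref = sets[0]
    dx, dy = [], []
    for pts in sets[1:]:
        _, _, _, res = align_similarity(ref, pts)
        dx.extend(np.abs(res[:, 0]))
        dy.extend(np.abs(res[:, 1]))
    return float(np.mean(dx)), float(np.mean(dy))


def displacement_over_cohort(
    per_fish_series: Mapping | Sequence,
) -> tuple[float, float]:
    """Displacement statistics averaged over several fish."""
    if isinstance(per_fish_series, Mapping):
        items = [per_fish_series[k] for k in sorted(per_fish_series)]
    else:
        items = list(per_fish_series)
    xs, ys = zip(*(displacement_analysis(s) for s in items))
    return float(np.mean(xs)), float(np.mean(ys))
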