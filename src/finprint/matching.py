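"""Trimmed nearest-neighbour matching of dot patterns.

The biometric distance between two dot patterns is computed by
translating the template pattern over a discrete shift grid (+/-30 px in
5-px steps for short-term matching, +/-50 px for long-term); at each
shift every query dot is matched to its nearest template dot, the
per-dot Euclidean distances are sorted, and the mean of the smallest
three quarters is taken - the largest quarter is discarded as outliers
(mis-detected dots).  The minimum over the grid is the final distance.
The shift search absorbs the residual ROI-localization error, which can
reach tens of pixels between two photographs of the same fish.

Identification is closed-set nearest-neighbour: the query is assigned
the gallery fish with the minimal final distance over that fish's
templates.  A count heuristic skips comparisons between patterns whose
dot counts differ by more than a factor of two.

For long-term matching each fish is enrolled as a *representative
pattern*: the subset of one reference pattern's dots that recur (within
20 px after shift alignment) in enough of the fish's images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .types import DotPattern, MatchResult, RepresentativePattern


@dataclass
class MatchConfig:
    """Shift-search and trimming parameters.

    ``max_shift`` is 30 px for short-term matching and 50 px for
    long-term; it must be a multiple of ``shift_step``.  ``scale_grid``
    optionally adds a uniform-scale search (about the template centroid)
    on top of the shift grid; it is off by default, matching the plain
    shift-only formulation.
    """

    max_shift: float = 30.0
    shift_step: float = 5.0
    trim_fraction: float = 0.75
    count_ratio_max: float = 2.0
    scale_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.trim_fraction <= 1.0):
            raise ValueError("trim_fraction must lie in (0, 1]")
        k = self.max_shift / self.shift_step
        if abs(k - round(k)) > 1e-9:
            raise ValueError("max_shift must be a multiple of shift_step")

    def shifts(self) -> np.ndarray:
        """Shift grid in lexicographic (dx, dy) order, e.g. 13x13 at 30/5."""
        s = np.arange(-self.max_shift, self.max_shift + self.shift_step / 2,
                      self.shift_step)
        dx, dy = np.meshgrid(s, s, indexing="ij")
        return np.column_stack([dx.ravel(), dy.ravel()])


SHORT_TERM = MatchConfig(max_shift=30.0)
LONG_TERM = MatchConfig(max_shift=50.0)


def _trim_count(n_query: int, trim_fraction: float) -> int:
    return max(int(np.ceil(trim_fraction * n_query)), 1)


def _as_points(p) -> np.ndarray:
    pts = p.points if hasattr(p, "points") else np.asarray(p, dtype=float)
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("empty dot pattern")
    return pts


def pattern_distance_at_shift(
    query, template, shift: tuple[float, float],
    trim_fraction: float = 0.75,
) -> float:
    """Trimmed mean nearest-neighbour distance at one fixed template shift."""
    q = _as_points(query)
    t = _as_points(template) + np.asarray(shift, dtype=float)
    d2 = ((q[:, None, :] - t[None, :, :]) ** 2).sum(-1)
    nn = np.sqrt(d2.min(axis=1))
    k = _trim_count(len(q), trim_fraction)
    return float(np.sort(nn)[:k].mean())


def pattern_distance(
    query, template, config: MatchConfig = SHORT_TERM
) -> tuple[float, tuple[float, float]]:
    """Minimum trimmed distance over the shift grid and its arg-min shift.

    Ties break toward the lexicographically smallest (dx, dy).  With
    ``config.scale_grid`` set, the template is additionally scaled about
    its centroid and the minimum is taken over scales too.
    """
    q = _as_points(query)
    t0 = _as_points(template)
    shifts = config.shifts()
    k = _trim_count(len(q), config.trim_fraction)
    scales = config.scale_grid or (1.0,)
    centroid = t0.mean(axis=0)

    best = np.inf
    best_shift = (0.0, 0.0)
    for s in scales:
        t = centroid + s * (t0 - centroid) if s != 1.0 else t0
        dx = q[:, 0:1] - t[None, :, 0]   # (nq, nt)
        dy = q[:, 1:2] - t[None, :, 1]
        # (n_shift, nq, nt) -> nearest template dot per query dot per shift
        d2 = (dx[None] - shifts[:, 0, None, None]) ** 2 \
            + (dy[None] - shifts[:, 1, None, None]) ** 2
        nn = np.sqrt(d2.min(axis=2))
        if k < nn.shape[1]:
            part = np.partition(nn, k - 1, axis=1)[:, :k]
        else:
            part = nn
        dists = part.mean(axis=1)
        i = int(np.argmin(dists))
        if dists[i] < best - 1e-15:
            best = float(dists[i])
            best_shift = (float(shifts[i, 0]), float(shifts[i, 1]))
    return best, best_shift


def comparable(a, b, count_ratio_max: float = 2.0) -> bool:
    """Count heuristic: dot counts must agree within the given factor."""
    na = len(a.points) if hasattr(a, "points") else len(a)
    nb = len(b.points) if hasattr(b, "points") else len(b)
    if min(na, nb) == 0:
        return False
    return max(na, nb) <= count_ratio_max * min(na, nb)


def _identify(
    query, gallery: Mapping, config: MatchConfig, query_id: str,
    true_id, session_pair: tuple[str, str],
) -> MatchResult:
    if not gallery:
        raise ValueError("empty gallery")
    distances: dict = {}
    best_shifts: dict = {}

    def run(use_heuristic: bool) -> None:
        for fid in sorted(gallery):
            templates = gallery[fid]
            if not isinstance(templates, (list, tuple)):
                templates = [templates]
            best, best_s = np.inf, (0.0, 0.0)
            for tpl in templates:
                if use_heuristic and not comparable(query, tpl,
                                                    config.count_ratio_max):
                    continue
                d, s = pattern_distance(query, tpl, config)
                if d < best:
                    best, best_s = d, s
            if np.isfinite(best):
                distances[fid] = best
                best_shifts[fid] = best_s

    run(use_heuristic=True)
    if not distances:
        # every fish was pruned by the count heuristic; compare against all
        run(use_heuristic=False)
    pred = min(sorted(distances), key=lambda f: distances[f])
    return MatchResult(query_id=query_id, true_id=true_id, predicted_id=pred,
                       distances=distances, best_shifts=best_shifts,
                       session_pair=session_pair)


def identify_short_term(
    query: DotPattern,
    gallery: Mapping[int, Sequence[DotPattern]],
    config: MatchConfig = SHORT_TERM,
) -> MatchResult:
    """Nearest-neighbour identification against per-fish template patterns."""
    return _identify(query, gallery, config,
                     query_id=query.image_id, true_id=query.fish_id,
                     session_pair=(query.session, query.session))


def build_representative(
    patterns: Sequence[DotPattern],
    config: MatchConfig = SHORT_TERM,
    accept_radius: float = 20.0,
    fish_id=None,
    session: str = "",
) -> RepresentativePattern:
    """Distill one fish's patterns into a consensus representative.

    The pattern with minimal mean distance to the others becomes the
    reference; every other pattern is aligned to it by its best grid
    shift; a reference dot is kept when at least ``max(3, floor(N/3)+1)``
    of the N patterns contain a point within ``accept_radius`` px of it
    (with fewer than three patterns everything is kept).  Kept dots
    retain the reference pattern's coordinates - the representative is a
    subset of detected dots, not an average.
    """
    pats = [p for p in patterns if len(p) > 0]
    n = len(pats)
    if n == 0:
        raise ValueError("no non-empty patterns to enroll")
    if n == 1:
        warnings.warn("single pattern; representative is a pass-through")
        return RepresentativePattern(
            points=pats[0].points.copy(), support=np.ones(len(pats[0]), int),
            n_source_patterns=1, fish_id=fish_id, session=session)

    mean_d = np.zeros(n)
    for i in range(n):
        ds = [pattern_distance(pats[j], pats[i], config)[0]
              for j in range(n) if j != i]
        mean_d[i] = np.mean(ds)
    ref_i = int(np.argmin(mean_d))
    ref = pats[ref_i].points

    aligned = []
    for j, p in enumerate(pats):
        if j == ref_i:
            aligned.append(p.points)
            continue
        _, shift = pattern_distance(p, pats[ref_i], config)
        # best shift moves the reference toward p; apply the inverse to p
        aligned.append(p.points - np.asarray(shift))

    support = np.zeros(len(ref), dtype=int)
    for pts in aligned:
        d = np.sqrt(((ref[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).min(axis=1)
        support += d < accept_radius
    threshold = max(3, n // 3 + 1)
    keep = support >= threshold if n >= 3 else np.ones(len(ref), bool)
    if not keep.any():
        # degenerate (wildly inconsistent detections): fall back to the
        # best-supported dots rather than an empty signature
        keep = support >= support.max()
    return RepresentativePattern(points=ref[keep], support=support[keep],
                                 n_source_patterns=n, fish_id=fish_id,
                                 session=session)


def identify_long_term(
    query: RepresentativePattern | DotPattern,
    gallery: Mapping[int, RepresentativePattern],
    config: MatchConfig = LONG_TERM,
    session_pair: tuple[str, str] = ("", ""),
) -> MatchResult:
    """Identify a representative pattern against a representative gallery."""
    q = query.as_pattern() if isinstance(query, RepresentativePattern) else query
    g = {fid: (rp.as_pattern() if isinstance(rp, RepresentativePattern) else rp)
         for fid, rp in gallery.items()}
    return _identify(q, g, config,
                     query_id=q.image_id or f"rep_f{q.fish_id}",
                     true_id=q.fish_id, session_pair=session_pair)
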