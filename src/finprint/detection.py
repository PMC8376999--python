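"""Dot localization in normalized ROIs.

Two interchangeable detectors produce a :class:`~finprint.types.DotPattern`:

* the trained 25x25 patch classifier scanned as a sliding window with a
  5-px step, keeping windows whose dot probability exceeds 0.30 and
  collapsing nearby hits by single-linkage clustering at 15 px;
* a deterministic Laplacian-of-Gaussian blob detector with the same
  output contract, useful when no trained model is at hand.

Both restrict detections to the posterior two thirds of the ROI
(window-center x >= 1000/3): the anterior third images the head, which
carries no melanophore pattern.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.feature import blob_log

from .cnn import PATCH_SIZE, PatchCNN
from .synthetic import PatchDataset
from .types import DotPattern, NormalizedROI

HEAD_FRACTION = 1.0 / 3.0
DEFAULT_STEP = 5
DEFAULT_P_MIN = 0.30
DEFAULT_CLUSTER_CUTOFF = 15.0


def train_patch_classifier(
    dataset: PatchDataset, seed: int = 0, **fit_kwargs
) -> tuple[PatchCNN, float]:
    """Train on the dataset's train split, report held-out test accuracy."""
    x_tr, y_tr = dataset.subset("train")
    x_te, y_te = dataset.subset("test")
    clf = PatchCNN(seed=seed)
    clf.fit(x_tr, y_tr, **fit_kwargs)
    if len(x_te):
        acc = float(np.mean(clf.predict(x_te) == y_te))
    else:
        acc = float("nan")
    return clf, acc


def classify_patch(classifier: PatchCNN, patch: np.ndarray) -> float:
    """Probability that a single 25x25 patch contains a dot."""
    return float(classifier.predict_proba(patch)[0, 1])


def cluster_detections(
    points: np.ndarray, cutoff: float = DEFAULT_CLUSTER_CUTOFF
) -> np.ndarray:
    """Single-linkage clustering with a distance cutoff; returns centroids.

    Points strictly closer than ``cutoff`` are chained into one cluster
    (single linkage chains: collinear points 10 px apart under a 15-px
    cutoff form a single cluster).  Output order follows each cluster's
    first member.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return pts.copy()
    if len(pts) == 1:
        return pts.copy()
    lk = linkage(pts, method="single")
    labels = fcluster(lk, t=np.nextafter(cutoff, 0.0), criterion="distance")
    order = []
    seen = set()
    for lab in labels:
        if lab not in seen:
            seen.add(lab)
            order.append(lab)
    return np.array([pts[labels == lab].mean(axis=0) for lab in order])


def detect_dots(
    roi: NormalizedROI,
    classifier: PatchCNN,
    step: int = DEFAULT_STEP,
    p_min: float = DEFAULT_P_MIN,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    return_candidates: bool = False,
    **meta,
) -> DotPattern:
    """Sliding-window scan of the ROI with the trained patch classifier.

    With ``return_candidates`` the un-clustered candidate window centers
    are returned alongside the pattern.
    """
    img = np.asarray(roi.image, dtype=np.float32)
    h, w = img.shape
    empty = DotPattern(np.empty((0, 2)), **meta)
    if h < PATCH_SIZE or w < PATCH_SIZE:
        warnings.warn("ROI smaller than one window; empty pattern")
        return (empty, np.empty((0, 2))) if return_candidates else empty
    half = (PATCH_SIZE - 1) / 2.0
    x_min_center = w * HEAD_FRACTION

    view = np.lib.stride_tricks.sliding_window_view(img, (PATCH_SIZE, PATCH_SIZE))
    view = view[::step, ::step]
    tls_y = np.arange(view.shape[0]) * step
    tls_x = np.arange(view.shape[1]) * step
    keep_x = tls_x + half >= x_min_center
    view = view[:, keep_x]
    tls_x = tls_x[keep_x]
    if view.size == 0:
        return (empty, np.empty((0, 2))) if return_candidates else empty

    flat = view.reshape(-1, PATCH_SIZE, PATCH_SIZE)
    probs = classifier.predict_proba(flat)[:, 1].reshape(view.shape[:2])
    iy, ix = np.nonzero(probs > p_min)
    centers = np.column_stack([tls_x[ix] + half, tls_y[iy] + half])
    pattern = DotPattern(cluster_detections(centers, cluster_cutoff), **meta)
    return (pattern, centers) if return_candidates else pattern


def detect_dots_blob(
    roi: NormalizedROI,
    min_sigma: float = 2.5,
    max_sigma: float = 5.5,
    n_sigma: int = 3,
    threshold: float = 0.12,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    **meta,
) -> DotPattern:
    """Deterministic Laplacian-of-Gaussian dot detector.

    The ROI is contrast-normalized by its median gray level, which makes
    the detector invariant to the session's illumination gain; blob
    centers are refined to the intensity-weighted centroid of the local
    darkness.  Output contract and head-region restriction are identical
    to :func:`detect_dots`.
    """
    img = np.asarray(roi.image, dtype=float)
    h, w = img.shape
    if h < 3 or w < 3:
        return DotPattern(np.empty((0, 2)), **meta)
    med = max(float(np.median(img)), 1.0)
    inv = np.clip((med - img) / med, 0.0, 1.0).astype(np.float32)
    blobs = blob_log(inv, min_sigma=min_sigma, max_sigma=max_sigma,
                     num_sigma=n_sigma, threshold=threshold)
    centers = []
    for y, x, sigma in blobs:
        r = max(int(round(1.8 * sigma)), 2)
        y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
        x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
        win = inv[y0:y1, x0:x1]
        wgt = win ** 2
        tot = wgt.sum()
        if tot <= 0:
            centers.append((x, y))
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        centers.append(((wgt * xx).sum() / tot, (wgt * yy).sum() / tot))
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    if len(centers):
        centers = centers[centers[:, 0] >= w * HEAD_FRACTION]
    if len(centers) == 0:
        return DotPattern(np.empty((0, 2)), **meta)
    return DotPattern(cluster_detections(centers, cluster_cutoff), **meta)
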