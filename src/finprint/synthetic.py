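"""Seeded generator of synthetic salmon images with ground truth.

Emulates the acquisition conditions of the identification study the
package implements: one fish per image, lateral head-left view on a
saturated green background, in-plane rotation within +/-45 degrees,
translation, per-session illumination changes, per-identity melanophore
dot maps (4-40 dots on the flank, none on the head), and anisotropic
growth across sessions (length up to x1.6, height up to x1.9).

The fish silhouette is a parametric profile, not a salmon mesh; it
guarantees exactly the features the landmark pipeline relies on: a
rounded head carrying a dark eye disk (gray intensity < 20), a straight
back leading into a triangular dorsal fin whose leading edge begins at
half the head-to-waist length, a belly directly below the fin base, a
unique narrowest pre-tail column, and an opaque tail fin.

Every render returns the applied affine transform, landmark positions
and true dot centroids so downstream stages can be validated against
exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, warp

from .types import FishImage

# ---------------------------------------------------------------------------
# Reference geometry. All s-values are fractions of the head-to-tail extent E;
# all heights are fractions of the reference extent E0 and scale with the
# height growth factor only, so length and height grow independently.
E0 = 720.0

_S_HEAD_TOP = 0.20  # head rounding ends (dorsal)
_S_HEAD_BOT = 0.22  # head rounding ends (ventral)
_S_FIN0 = 0.42      # dorsal fin leading-edge base  (= UP ground truth)
_S_FIN_APEX = 0.55
_S_FIN1 = 0.62
_S_TAPER = 0.64     # dorsal taper toward the waist begins
_S_WAIST = 0.84     # narrowest pre-tail column      (= NP ground truth)

_H_BACK = 0.125
_H_FIN = 0.055
_H_BELLY = 0.1472
_H_WAIST = 0.032
_H_TAIL = 0.105

_EYE_S = 0.07
_EYE_R = 0.016
_EYE_DY = -0.030    # eye center above the body axis

_PAD = 6.0          # template margin around the silhouette

#: Standard width of the normalized ROI, px.
ROI_WIDTH = 1000
#: Nominal normalized-ROI height implied by the reference geometry, px.
ROI_NOMINAL_HEIGHT = 271

#: Margin (normalized-ROI px) kept between dots and the ROI border.
_DOT_MARGIN = 18.0
#: Minimum inter-dot spacing in normalized-ROI px.  Chosen well above the
#: 15-px detection clustering cutoff so clustering can never merge two
#: distinct true dots even after jitter.
MIN_DOT_SPACING = 32.0

BACKGROUND_RGB = (44, 178, 72)  # saturated green, hue ~128 deg


@dataclass
class SyntheticIdentity:
    """One fish's immutable dot map in unit flank coordinates.

    ``u`` runs 0-1 along the body axis over the ROI span (eye to fin
    base), ``v`` 0-1 over the ROI height.  No dots occur at u < 1/3 (the
    head third carries no pattern).
    """

    fish_id: int
    body_dots: np.ndarray          # (n, 2) float in [0,1]^2
    dot_radius: np.ndarray         # (n,) px at reference (normalized-ROI) size
    dot_contrast: np.ndarray       # (n,) relative intensity drop, 0-1

    def __post_init__(self) -> None:
        self.body_dots = np.asarray(self.body_dots, dtype=float).reshape(-1, 2)
        self.dot_radius = np.asarray(self.dot_radius, dtype=float).reshape(-1)
        self.dot_contrast = np.asarray(self.dot_contrast, dtype=float).reshape(-1)

    @property
    def n_dots(self) -> int:
        return len(self.body_dots)


@dataclass
class SceneParams:
    """Per-image acquisition conditions."""

    rotation_deg: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)
    illumination_gain: float = 1.0
    growth_factor_length: float = 1.0
    growth_factor_height: float = 1.0
    blur_sigma: float = 0.0
    dot_jitter_sd: float = 0.0   # between-session dot drift, normalized-ROI px
    session: str = "SS"

    def __post_init__(self) -> None:
        if abs(self.rotation_deg) > 45.0 + 1e-9:
            raise ValueError("rotation_deg must lie within +/-45 degrees")
        if not (1.0 - 1e-9 <= self.growth_factor_length <= 1.6 + 1e-9):
            raise ValueError("growth_factor_length must lie in [1.0, 1.6]")
        if not (1.0 - 1e-9 <= self.growth_factor_height <= 1.9 + 1e-9):
            raise ValueError("growth_factor_height must lie in [1.0, 1.9]")


@dataclass
class PatchDataset:
    """Labeled 25x25 patches for training the dot/no-dot classifier."""

    patches: np.ndarray   # (N, 25, 25) float 0-255
    labels: np.ndarray    # (N,) int, 1 = dot
    split: np.ndarray     # (N,) str, 'train' or 'test'

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == which
        return self.patches[m], self.labels[m]


# ---------------------------------------------------------------------------
# identity generation

def generate_identity(
    seed: int,
    n_dots_range: tuple[int, int] = (8, 30),
    fish_id: Optional[int] = None,
) -> SyntheticIdentity:
    """Draw one fish identity: a dot map with enforced minimum spacing.

    Deterministic for a fixed seed.  Dot centers are dart-thrown in the
    flank region u in [1/3, 1] with pairwise spacing of at least
    :data:`MIN_DOT_SPACING` normalized-ROI pixels.
    """
    lo, hi = int(n_dots_range[0]), int(n_dots_range[1])
    if lo < 4 or hi > 40 or lo > hi:
        raise ValueError("n_dots_range must satisfy 4 <= min <= max <= 40")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(lo, hi + 1))

    u_lo = 1.0 / 3.0 + _DOT_MARGIN / ROI_WIDTH
    u_hi = 1.0 - _DOT_MARGIN / ROI_WIDTH
    v_lo = _DOT_MARGIN / ROI_NOMINAL_HEIGHT
    v_hi = 1.0 - _DOT_MARGIN / ROI_NOMINAL_HEIGHT

    pts: list[np.ndarray] = []
    px = np.empty((0, 2))
    attempts = 0
    while len(pts) < n:
        cand = np.array([rng.uniform(u_lo, u_hi), rng.uniform(v_lo, v_hi)])
        cand_px = cand * (ROI_WIDTH, ROI_NOMINAL_HEIGHT)
        if len(pts) == 0 or np.min(np.hypot(*(px - cand_px).T)) >= MIN_DOT_SPACING:
            pts.append(cand)
            px = np.vstack([px, cand_px])
        attempts += 1
        if attempts > 4000:  # region is far from saturated at n <= 40
            raise RuntimeError("dot placement failed to satisfy spacing")
    dots = np.array(pts)
    return SyntheticIdentity(
        fish_id=int(fish_id if fish_id is not None else seed),
        body_dots=dots,
        dot_radius=rng.uniform(4.5, 6.5, size=n),
        dot_contrast=rng.uniform(0.5, 0.75, size=n),
    )


# ---------------------------------------------------------------------------
# silhouette profiles

def _half_heights(s: np.ndarray, gh: float) -> tuple[np.ndarray, np.ndarray]:
    """Dorsal and ventral half-height profiles (px) along s in [0, 1]."""
    k = E0 * gh
    back, fin, belly, waist, tail = (
        _H_BACK * k, (_H_BACK + _H_FIN) * k, _H_BELLY * k, _H_WAIST * k, _H_TAIL * k)

    top = np.interp(
        s,
        [_S_HEAD_TOP, _S_FIN0, _S_FIN_APEX, _S_FIN1, _S_TAPER, _S_WAIST, 1.0],
        [back, back, fin, back, back, waist, tail],
    )
    head = s < _S_HEAD_TOP
    top = np.where(
        head,
        back * np.sqrt(np.clip(1 - ((_S_HEAD_TOP - s) / _S_HEAD_TOP) ** 2, 0, 1)),
        top,
    )
    bot = np.interp(
        s,
        [_S_HEAD_BOT, _S_TAPER - 0.02, _S_WAIST, 1.0],
        [belly, belly, waist, tail],
    )
    headb = s < _S_HEAD_BOT
    bot = np.where(
        headb,
        belly * np.sqrt(np.clip(1 - ((_S_HEAD_BOT - s) / _S_HEAD_BOT) ** 2, 0, 1)),
        bot,
    )
    return top, bot


def template_landmarks(scene: SceneParams) -> dict:
    """Ground-truth landmark positions in the axis-aligned template frame."""
    gl, gh = scene.growth_factor_length, scene.growth_factor_height
    E = E0 * gl
    k = E0 * gh
    axis_y = _PAD + (_H_BACK + _H_FIN) * k

    def x(s: float) -> float:
        return _PAD + s * E

    up = (x(_S_FIN0), axis_y - _H_BACK * k)
    bp = (x(_S_FIN0), axis_y + _H_BELLY * k)
    ep = (x(_EYE_S), axis_y + _EYE_DY * k)
    tip = (_PAD, axis_y)
    np_pt = (x(_S_WAIST), axis_y)
    # ROI bounds per the landmark formula, in the template/bbox frame
    # (the template's silhouette bounding box starts at (_PAD, _PAD)).
    bbox_top = _PAD
    up_b, bp_b = up[1] - bbox_top, bp[1] - bbox_top
    roi_top = bbox_top + up_b + (bp_b - up_b) / 20.0
    roi_bottom = bbox_top + bp_b / 2.0
    return {
        "EP": ep, "UP": up, "BP": bp, "NP": np_pt, "tip": tip,
        "axis_y": axis_y, "extent": E,
        "roi_rect": (ep[0], up[0], roi_top, roi_bottom),  # x0, x1, y0, y1
    }


def dots_template_xy(identity_dots: np.ndarray, scene: SceneParams) -> np.ndarray:
    """Map unit flank coordinates (u, v) to template-frame pixels."""
    lm = template_landmarks(scene)
    x0, x1, y0, y1 = lm["roi_rect"]
    d = np.asarray(identity_dots, dtype=float).reshape(-1, 2)
    out = np.empty_like(d)
    out[:, 0] = lm["EP"][0] + d[:, 0] * (lm["UP"][0] - lm["EP"][0])
    out[:, 1] = y0 + d[:, 1] * (y1 - y0)
    return out


def _render_template(
    identity: SyntheticIdentity, scene: SceneParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render the axis-aligned fish (float gray 0-255) plus mask and truth."""
    gl, gh = scene.growth_factor_length, scene.growth_factor_height
    E = E0 * gl
    k = E0 * gh
    lm = template_landmarks(scene)
    axis_y = lm["axis_y"]

    W = int(np.ceil(E + 2 * _PAD))
    H = int(np.ceil((_H_BACK + _H_FIN) * k + _H_BELLY * k + 2 * _PAD))
    yy, xx = np.mgrid[0:H, 0:W]
    s = np.clip((xx - _PAD) / E, 0.0, 1.0)
    top, bot = _half_heights(s, gh)
    inside_x = (xx >= _PAD) & (xx <= _PAD + E)
    dy = yy - axis_y
    mask = inside_x & (dy >= -top) & (dy <= bot)

    # silvery skin: vertical shading + band-limited texture
    base = 168.0 - 24.0 * (dy / (_H_BELLY * k))
    low = rng.normal(0.0, 1.0, (H // 5 + 2, W // 5 + 2))
    low = ndi.zoom(low, 5, order=1)[:H, :W]
    tex = 6.0 * low + rng.normal(0.0, 1.5, (H, W))
    gray = np.clip(base + tex, 90.0, 235.0)

    # eye disk, intensity well below the 20-gray eye threshold
    ex, ey = lm["EP"]
    er = _EYE_R * k
    d_eye = np.hypot(xx - ex, yy - ey)
    eye_cov = np.clip((er - d_eye) / 1.5 + 0.5, 0.0, 1.0)
    gray = gray * (1 - eye_cov) + 8.0 * eye_cov

    # melanophore dots: soft-edged dark ellipses on the flank
    dot_xy = dots_template_xy(identity.body_dots, scene)
    roi_scale = (lm["UP"][0] - lm["EP"][0]) / ROI_WIDTH  # template px per ROI px
    for (cx, cy), r_roi, c in zip(dot_xy, identity.dot_radius, identity.dot_contrast):
        r = max(r_roi * roi_scale, 1.0)
        x_lo, x_hi = int(cx - r - 3), int(cx + r + 4)
        y_lo, y_hi = int(cy - r - 3), int(cy + r + 4)
        sub_y, sub_x = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        d = np.hypot(sub_x - cx, sub_y - cy)
        cov = np.clip((r - d) / max(0.8, r * 0.6) + 0.5, 0.0, 1.0)
        gray[y_lo:y_hi, x_lo:x_hi] *= 1 - c * cov

    gray[~mask] = 0.0
    truth = {"landmarks": lm, "dots_template": dot_xy}
    return gray.astype(np.float32), mask, truth


def _auto_canvas(scene: SceneParams, margin: float = 16.0) -> tuple[int, int]:
    """Canvas large enough for any rotation up to |scene.rotation_deg|.

    The rotated-bbox width E*cos(t) + H*sin(t) peaks at t = atan(H/E),
    inside the +/-45-degree range, so the maximum over the allowed range
    is taken rather than the value at the extreme angle.
    """
    lm = template_landmarks(scene)
    E = lm["extent"] + 2 * _PAD
    H = (_H_BACK + _H_FIN + _H_BELLY) * E0 * scene.growth_factor_height + 2 * _PAD
    r = np.deg2rad(abs(scene.rotation_deg))

    def extent(a: float, b: float) -> float:
        t_opt = np.arctan2(b, a)
        t = min(t_opt, r)
        return a * np.cos(t) + b * np.sin(t)

    tx, ty = scene.translation_px
    side_w = int(np.ceil(extent(E, H) + 2 * (margin + abs(tx))))
    side_h = int(np.ceil(extent(H, E) + 2 * (margin + abs(ty))))
    return side_w, side_h


def render_image(
    identity: SyntheticIdentity,
    scene: SceneParams,
    canvas_size: Optional[tuple[int, int]] = None,
    rng: Optional[np.random.Generator] = None,
    image_id: str = "",
    include_mask: bool = True,
) -> FishImage:
    """Render one fish on a green canvas and return it with ground truth.

    Raises ``ValueError`` if the rotated fish does not fit the canvas.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    gray_t, mask_t, truth_t = _render_template(identity, scene, rng)
    Ht, Wt = gray_t.shape
    if canvas_size is None:
        canvas_size = _auto_canvas(scene)
    W, H = int(canvas_size[0]), int(canvas_size[1])

    theta = np.deg2rad(scene.rotation_deg)
    tx, ty = scene.translation_px
    center_t = np.array([(Wt - 1) / 2.0, (Ht - 1) / 2.0])
    center_c = np.array([(W - 1) / 2.0 + tx, (H - 1) / 2.0 + ty])
    # skimage composes left-to-right: shift to origin, rotate, place on canvas
    A = (
        AffineTransform(translation=-center_t)
        + AffineTransform(rotation=theta)
        + AffineTransform(translation=center_c)
    )

    # verify the silhouette fits
    corners = np.array([[0, 0], [Wt - 1, 0], [0, Ht - 1], [Wt - 1, Ht - 1]], float)
    cc = A(corners)
    if cc[:, 0].min() < 0 or cc[:, 1].min() < 0 or cc[:, 0].max() > W - 1 or cc[:, 1].max() > H - 1:
        raise ValueError("fish exceeds canvas; enlarge canvas_size")

    warped_gray = warp(gray_t, A.inverse, output_shape=(H, W), order=1,
                       preserve_range=True, cval=0.0)
    alpha = warp(mask_t.astype(np.float64), A.inverse, output_shape=(H, W),
                 order=1, preserve_range=True, cval=0.0)

    warped_gray = warped_gray.astype(np.float32)
    alpha = alpha.astype(np.float32)
    img = np.empty((H, W, 3), dtype=np.float32)
    tint = (0.97, 1.0, 1.04)
    for ch in range(3):
        img[..., ch] = (BACKGROUND_RGB[ch] * (1 - alpha)
                        + warped_gray * tint[ch] * alpha)
    img *= scene.illumination_gain
    if scene.blur_sigma > 0:
        img = ndi.gaussian_filter(img, (scene.blur_sigma, scene.blur_sigma, 0))
    img += rng.normal(0.0, 1.2, img.shape).astype(np.float32)
    img = np.clip(img, 0, 255).astype(np.uint8)

    lm = truth_t["landmarks"]
    named = {n: np.asarray(A(np.array(lm[n])[None]))[0] for n in
             ("EP", "UP", "BP", "NP", "tip")}
    truth = {
        "landmarks_canvas": {n: p.tolist() for n, p in named.items()},
        "dots_canvas": np.asarray(A(truth_t["dots_template"])),
        "dots_unit": identity.body_dots.copy(),
        "affine_template_to_canvas": np.asarray(A.params),
        "scene": asdict(scene),
        "roi_rect_template": lm["roi_rect"],
    }
    if include_mask:
        truth["mask"] = alpha > 0.5
    return FishImage(
        image=img,
        fish_id=identity.fish_id,
        session=scene.session,
        image_id=image_id or f"f{identity.fish_id}_{scene.session}",
        truth=truth,
    )


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class ImageSpec:
    """Deferred-rendering description of one cohort image."""

    fish_id: int
    session: str
    image_id: str
    scene: SceneParams
    dots: np.ndarray         # unit coords with session + image jitter applied
    noise_seed: int


@dataclass
class Cohort:
    """A rendered-on-demand synthetic dataset with full ground truth."""

    identities: dict = field(default_factory=dict)  # fish_id -> SyntheticIdentity
    specs: list = field(default_factory=list)       # list[ImageSpec]
    canvas_by_session: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.specs)

    def render(self, i: int, include_mask: bool = True) -> FishImage:
        spec = self.specs[i]
        ident = self.identities[spec.fish_id]
        jittered = SyntheticIdentity(
            fish_id=ident.fish_id, body_dots=spec.dots,
            dot_radius=ident.dot_radius, dot_contrast=ident.dot_contrast)
        return render_image(
            jittered, spec.scene,
            canvas_size=self.canvas_by_session[spec.session],
            rng=np.random.default_rng(spec.noise_seed),
            image_id=spec.image_id, include_mask=include_mask)

    def __iter__(self) -> Iterator[FishImage]:
        for i in range(len(self.specs)):
            yield self.render(i)

    def save(self, out_dir: str | Path) -> Path:
        """Write PNGs, JSON ground-truth sidecars and a manifest CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = ["image_path,image_id,fish_id,session"]
        for i, spec in enumerate(self.specs):
            fi = self.render(i, include_mask=False)
            png = out / f"{spec.image_id}.png"
            iio.imwrite(png, fi.image)
            sidecar = {
                "fish_id": fi.fish_id, "session": fi.session,
                "image_id": fi.image_id,
                "landmarks_canvas": fi.truth["landmarks_canvas"],
                "dots_canvas": fi.truth["dots_canvas"].tolist(),
                "scene": fi.truth["scene"],
            }
            (out / f"{spec.image_id}.json").write_text(json.dumps(sidecar))
            rows.append(f"{png.name},{spec.image_id},{fi.fish_id},{fi.session}")
        manifest = out / "manifest.csv"
        manifest.write_text("\n".join(rows) + "\n")
        return manifest


def _jitter_unit(dots: np.ndarray, sd_px: float, rng: np.random.Generator) -> np.ndarray:
    """Jitter dots given an isotropic sd in normalized-ROI pixels."""
    if sd_px <= 0:
        return dots.copy()
    d = dots + rng.normal(0.0, sd_px, dots.shape) / (ROI_WIDTH, ROI_NOMINAL_HEIGHT)
    d[:, 0] = np.clip(d[:, 0], 1 / 3 + _DOT_MARGIN / ROI_WIDTH,
                      1 - _DOT_MARGIN / ROI_WIDTH)
    d[:, 1] = np.clip(d[:, 1], _DOT_MARGIN / ROI_NOMINAL_HEIGHT,
                      1 - _DOT_MARGIN / ROI_NOMINAL_HEIGHT)
    return d


def long_term_sessions(
    n_sessions: int = 4,
    dot_jitter_sd: float = 4.5,
    length_growth: float = 1.6,
    height_growth: float = 1.9,
) -> list[SceneParams]:
    """Session templates emulating the 6-month growth series SL1..SL4.

    Growth is interpolated geometrically so the final session reaches the
    full x1.6 length / x1.9 height change.
    """
    gains = [1.0, 1.08, 0.94, 1.03]
    out = []
    for k in range(n_sessions):
        f = k / max(n_sessions - 1, 1)
        out.append(SceneParams(
            session=f"SL{k + 1}",
            growth_factor_length=length_growth ** f,
            growth_factor_height=height_growth ** f,
            illumination_gain=gains[k % len(gains)],
            dot_jitter_sd=dot_jitter_sd,
        ))
    return out


def generate_cohort(
    n_fish: int,
    images_per_fish: int = 3,
    sessions: Optional[Sequence[SceneParams]] = None,
    seed: int = 0,
    n_dots_range: tuple[int, int] = (8, 30),
    rotation_range: float = 45.0,
    translation_max: float = 18.0,
    image_jitter_sd: float = 0.0,
) -> Cohort:
    """Generate a full experiment: identities x sessions x repeat images.

    Each image draws independent rotation (uniform within
    ``+/-rotation_range``), translation and a small illumination factor.
    Dot positions drift between sessions by the session's
    ``dot_jitter_sd`` (normalized-ROI px) and, optionally, per image by
    ``image_jitter_sd`` to emulate residual detection/pose noise.
    """
    if sessions is None:
        sessions = [SceneParams(session="SS")]
    rng = np.random.default_rng(seed)
    cohort = Cohort()
    for sess in sessions:
        cohort.canvas_by_session[sess.session] = _auto_canvas(
            SceneParams(rotation_deg=45.0,
                        translation_px=(translation_max, translation_max),
                        growth_factor_length=sess.growth_factor_length,
                        growth_factor_height=sess.growth_factor_height,
                        session=sess.session))
    for fid in range(n_fish):
        ident = generate_identity(
            int(rng.integers(0, 2**31 - 1)), n_dots_range, fish_id=fid)
        cohort.identities[fid] = ident
        for sess in sessions:
            sess_dots = _jitter_unit(ident.body_dots, sess.dot_jitter_sd, rng)
            for j in range(images_per_fish):
                dots = _jitter_unit(sess_dots, image_jitter_sd, rng)
                scene = SceneParams(
                    rotation_deg=float(rng.uniform(-rotation_range, rotation_range)),
                    translation_px=(float(rng.uniform(-translation_max, translation_max)),
                                    float(rng.uniform(-translation_max, translation_max))),
                    illumination_gain=sess.illumination_gain
                    * float(rng.uniform(0.93, 1.07)),
                    growth_factor_length=sess.growth_factor_length,
                    growth_factor_height=sess.growth_factor_height,
                    blur_sigma=sess.blur_sigma,
                    dot_jitter_sd=sess.dot_jitter_sd,
                    session=sess.session,
                )
                cohort.specs.append(ImageSpec(
                    fish_id=fid, session=sess.session,
                    image_id=f"f{fid:04d}_{sess.session}_{j}",
                    scene=scene, dots=dots,
                    noise_seed=int(rng.integers(0, 2**31 - 1))))
    return cohort


# ---------------------------------------------------------------------------
# training patches

def generate_patches(n_per_class: int = 535, seed: int = 0,
                     patch_size: int = 25) -> PatchDataset:
    """Balanced 25x25 dot / no-dot patches with a deterministic 2/3-1/3 split.

    Patches are cropped from actual rendered fish images after the full
    ROI extraction chain (segmentation, de-skew, landmark localization,
    width normalization), so the classifier trains on exactly the kind
    of content a sliding window will see.  Dot patches are centered on a
    ground-truth dot within +/-3 px; no-dot patches are skin crops at
    least 20 px from every dot.  The per-class test share is
    ``floor(n/3)``, so 535+535 patches split 714 train / 356 test.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    from . import roi as roi_mod  # local import: roi does not import back

    rng = np.random.default_rng(seed)
    ps = patch_size
    half = ps // 2
    dots: list[np.ndarray] = []
    bgs: list[np.ndarray] = []
    k = 0
    while (len(dots) < n_per_class or len(bgs) < n_per_class) and k < 500:
        ident = generate_identity(int(rng.integers(0, 2**31 - 1)),
                                  (15, 35), fish_id=k)
        scene = SceneParams(
            rotation_deg=float(rng.uniform(-45, 45)),
            translation_px=(float(rng.uniform(-15, 15)),
                            float(rng.uniform(-15, 15))),
            illumination_gain=float(rng.uniform(0.93, 1.07)))
        fi = render_image(ident, scene, include_mask=False,
                          rng=np.random.default_rng(int(rng.integers(2**31))))
        nroi, obj = roi_mod.extract_normalized_roi(fi)
        img = nroi.image
        h, w = img.shape
        gt = nroi.project(obj.to_object(fi.truth["dots_canvas"]))
        for cx, cy in gt:
            if len(dots) >= n_per_class:
                break
            x = int(round(cx + rng.uniform(-3, 3))) - half
            y = int(round(cy + rng.uniform(-3, 3))) - half
            if 0 <= x <= w - ps and 0 <= y <= h - ps:
                dots.append(img[y:y + ps, x:x + ps].astype(float))
        for _ in range(len(gt)):
            if len(bgs) >= n_per_class:
                break
            x = int(rng.integers(0, w - ps + 1))
            y = int(rng.integers(0, h - ps + 1))
            center = np.array([x + half, y + half])
            if np.min(np.hypot(*(gt - center).T)) >= 20.0:
                bgs.append(img[y:y + ps, x:x + ps].astype(float))
        k += 1

    patches = np.empty((2 * n_per_class, ps, ps), dtype=float)
    labels = np.empty(2 * n_per_class, dtype=int)
    for i in range(n_per_class):
        patches[2 * i], labels[2 * i] = bgs[i], 0
        patches[2 * i + 1], labels[2 * i + 1] = dots[i], 1

    order = rng.permutation(2 * n_per_class)
    patches, labels = patches[order], labels[order]
    split = np.full(2 * n_per_class, "train", dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_test = n_per_class // 3
        split[idx[:n_test]] = "test"
    return PatchDataset(patches=patches, labels=labels, split=split.astype(str))
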