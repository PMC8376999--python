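"""Fish segmentation, de-skew, landmark localization and ROI extraction.

The chain mirrors the acquisition protocol the package targets: the fish
is photographed laterally on a green background, so the background is
found by hue/saturation thresholding, the fish is the largest non-green
object, and it is de-skewed with its second-moment (ellipse) orientation.
Landmarks are then found in the de-skewed frame:

* NP - the column of the narrowest pre-tail width (the tail fin itself is
  semi-transparent in real data and unreliable to segment, so fish length
  is defined head tip to NP);
* UP - the beginning of the upper (dorsal) fin, located by fitting lines
  to the left and right halves of the upper body border within 3/8-5/8 of
  the fish length and intersecting them;
* EP - the eye centroid, all gray pixels below intensity 20 in the head
  third;
* BP - the belly border directly below UP.

The ROI is the rectangle x in [EP.x, UP.x], y in [UP.y + (BP.y-UP.y)/20,
BP.y/2] (fish-object frame, origin at the bounding-box top-left), and is
resampled to the standard 1000-px width for dot detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, resize, warp

from .types import FishImage, FishObject, Landmarks, NormalizedROI

EYE_THRESHOLD = 20.0
ROI_WIDTH = 1000

#: gray value used for pixels that fall outside the source frame when the
#: crop is rotated; bright, so it can never masquerade as eye pixels.
_FILL_GRAY = 210.0


class NoFishError(ValueError):
    pass


class EyeNotFoundError(ValueError):
    pass


class DegenerateROIError(ValueError):
    pass


@dataclass
class ROIConfig:
    """Segmentation thresholds; the defaults match the synthetic scenes.

    Hue is in degrees on the hue/saturation/lightness wheel; real
    deployments recalibrate to their own backdrop.
    """

    hue_min: float = 90.0
    hue_max: float = 150.0
    sat_min: float = 0.30
    eye_threshold: float = EYE_THRESHOLD
    roi_width: int = ROI_WIDTH


def _rgb_to_hsl(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hue (degrees), HSL saturation and lightness, vectorized."""
    rgb = image.astype(np.float32) / np.float32(255.0)
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    c = mx - mn
    ll = (mx + mn) * np.float32(0.5)
    s = c / (1.0 - np.abs(2.0 * ll - 1.0) + np.float32(1e-6))

    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    cs = c + np.float32(1e-12)
    h = np.where(mx == r, np.mod((g - b) / cs, 6.0),
                 np.where(mx == g, (b - r) / cs + 2.0, (r - g) / cs + 4.0))
    h = np.where(c > 1e-12, h * 60.0, 0.0)
    return h, s, ll


def to_gray(image: np.ndarray) -> np.ndarray:
    """8-bit-scale luminance (Rec.601 weights), float."""
    rgb = image.astype(np.float32)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def segment_background(
    image: np.ndarray | FishImage, config: ROIConfig | None = None
) -> np.ndarray:
    """Boolean mask of green-background pixels (True = background)."""
    if isinstance(image, FishImage):
        image = image.image
    cfg = config or ROIConfig()
    h, s, _ = _rgb_to_hsl(image)
    return (h >= cfg.hue_min) & (h <= cfg.hue_max) & (s >= cfg.sat_min)


def locate_fish(
    bg_mask: np.ndarray, image: np.ndarray | FishImage | None = None
) -> FishObject:
    """Largest connected non-background component, holes filled."""
    if isinstance(image, FishImage):
        image = image.image
    fg = ~bg_mask
    labels, n = ndi.label(fg)
    if n == 0:
        raise NoFishError("no fish found: empty foreground")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    mask = ndi.binary_fill_holes(labels == best)
    if not mask.any():
        raise NoFishError("no fish found: empty component")
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    mask_c = mask[y0:y1, x0:x1]
    if image is not None:
        rgb = image[y0:y1, x0:x1].copy()
        gray = to_gray(rgb)
    else:
        rgb = None
        gray = np.full(mask_c.shape, _FILL_GRAY)
    tf = np.eye(3)
    tf[0, 2] = -x0
    tf[1, 2] = -y0
    return FishObject(mask=mask_c, gray=gray, rgb=rgb, transform=tf)


def mask_orientation_deg(mask: np.ndarray) -> float:
    """Second-moment (ellipse-equivalent) major-axis angle vs the x axis.

    Degrees in (-90, 90], y down; 0 means horizontal.  Returns 0 for
    degenerate (isotropic) objects.
    """
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    if abs(mu11) < 1e-9 and abs(mu20 - mu02) < 1e-9:
        return 0.0
    return float(np.degrees(0.5 * np.arctan2(2 * mu11, mu20 - mu02)))


def _rotate_object(obj: FishObject, angle_deg: float) -> FishObject:
    """Rotate the object frame by ``angle_deg`` about its center, re-crop."""
    h, w = obj.mask.shape
    theta = np.deg2rad(angle_deg)
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    rot = AffineTransform(rotation=theta)
    cc = rot(corners - center)
    out_w = int(np.ceil(cc[:, 0].max() - cc[:, 0].min())) + 3
    out_h = int(np.ceil(cc[:, 1].max() - cc[:, 1].min())) + 3
    new_center = np.array([(out_w - 1) / 2.0, (out_h - 1) / 2.0])
    fwd = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=theta)
        + AffineTransform(translation=new_center)
    )
    mask = warp(obj.mask.astype(float), fwd.inverse, output_shape=(out_h, out_w),
                order=1, preserve_range=True, cval=0.0) > 0.5
    gray = warp(obj.gray, fwd.inverse, output_shape=(out_h, out_w),
                order=1, preserve_range=True, cval=_FILL_GRAY)
    rgb = None
    if obj.rgb is not None:
        rgb = warp(obj.rgb.astype(float), fwd.inverse,
                   output_shape=(out_h, out_w), order=1,
                   preserve_range=True, cval=_FILL_GRAY)
    if not mask.any():
        raise NoFishError("object vanished during rotation")
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    crop_tf = np.eye(3)
    crop_tf[0, 2] = -x0
    crop_tf[1, 2] = -y0
    tf = crop_tf @ np.asarray(fwd.params) @ obj.transform
    return FishObject(
        mask=mask[y0:y1, x0:x1],
        gray=gray[y0:y1, x0:x1],
        rgb=None if rgb is None else rgb[y0:y1, x0:x1],
        orientation_applied_deg=obj.orientation_applied_deg + angle_deg,
        transform=tf,
    )


def _flip_180(obj: FishObject) -> FishObject:
    h, w = obj.mask.shape
    flip = np.array([[-1.0, 0.0, w - 1.0], [0.0, -1.0, h - 1.0], [0.0, 0.0, 1.0]])
    return FishObject(
        mask=obj.mask[::-1, ::-1].copy(),
        gray=obj.gray[::-1, ::-1].copy(),
        rgb=None if obj.rgb is None else obj.rgb[::-1, ::-1].copy(),
        orientation_applied_deg=obj.orientation_applied_deg + 180.0,
        transform=flip @ obj.transform,
    )


def deskew(obj: FishObject, eye_threshold: float = EYE_THRESHOLD) -> FishObject:
    """Rotate the object horizontal and standardize it head-left.

    The head side is decided by where the sub-threshold (eye) pixels sit;
    if no eye pixels are found the wider (head) half is used.
    """
    angle = mask_orientation_deg(obj.mask)
    out = _rotate_object(obj, -angle)

    w = out.mask.shape[1]
    dark = (out.gray < eye_threshold) & out.mask
    if dark.any():
        xs = np.nonzero(dark)[1]
        head_left = np.median(xs) < w / 2.0
    else:
        half = w // 2
        head_left = out.mask[:, :half].sum() >= out.mask[:, half:].sum()
    if not head_left:
        out = _flip_180(out)
    return out


def find_narrowest(obj: FishObject, tail_margin: float = 0.05) -> int:
    """Column of minimal vertical mask extent in the posterior half.

    Ties are broken toward the rightmost minimal column.  The trailing
    ``tail_margin`` fraction of columns is excluded: the tail fin's own
    trailing edge always tapers to narrow corner columns that would
    otherwise win over the true pre-tail waist.
    """
    h, w = obj.mask.shape
    any_col = obj.mask.any(axis=0)
    top = np.argmax(obj.mask, axis=0)
    bottom = h - 1 - np.argmax(obj.mask[::-1], axis=0)
    extent = np.where(any_col, bottom - top + 1, np.iinfo(np.int64).max)
    lo = w // 2
    hi = max(lo + 1, w - int(np.ceil(tail_margin * w)))
    ext = extent[lo:hi]
    best_rev = len(ext) - 1 - int(np.argmin(ext[::-1]))
    return lo + best_rev


def find_upper_fin(obj: FishObject, length_px: float) -> tuple[float, float]:
    """Intersect line fits to the upper border left/right of the window center.

    The search window is 3/8..5/8 of the fish length; the border is the
    topmost mask pixel per column.  Falls back to the highest border
    point when the fitted lines are (near) parallel.
    """
    lo = int(np.ceil(3.0 / 8.0 * length_px))
    hi = int(np.floor(5.0 / 8.0 * length_px))
    cols = np.arange(lo, hi + 1)
    cols = cols[(cols >= 0) & (cols < obj.mask.shape[1])]
    cols = cols[obj.mask[:, cols].any(axis=0)]
    if len(cols) < 4:
        raise NoFishError("upper-fin window contains no border")
    y_top = np.argmax(obj.mask[:, cols], axis=0).astype(float)
    xc = (cols[0] + cols[-1]) / 2.0
    left = cols <= xc
    right = ~left
    if left.sum() < 2 or right.sum() < 2:
        i = int(np.argmin(y_top))
        return float(cols[i]), float(y_top[i])
    a1, b1 = np.polyfit(cols[left], y_top[left], 1)
    a2, b2 = np.polyfit(cols[right], y_top[right], 1)
    if abs(a1 - a2) < 1e-6:
        i = int(np.argmin(y_top))
        return float(cols[i]), float(y_top[i])
    x_star = (b2 - b1) / (a1 - a2)
    return float(x_star), float(a1 * x_star + b1)


def find_eye(
    obj: FishObject, UP: tuple[float, float], eye_threshold: float = EYE_THRESHOLD
) -> tuple[float, float]:
    """Centroid of gray < threshold pixels within x in [0, UP.x/3]."""
    x_hi = int(np.floor(UP[0] / 3.0))
    region = obj.gray[:, : x_hi + 1]
    dark = region < eye_threshold
    if not dark.any():
        raise EyeNotFoundError("eye not found: no pixel below threshold")
    ys, xs = np.nonzero(dark)
    return float(xs.mean()), float(ys.mean())


def find_belly(obj: FishObject, UP: tuple[float, float]) -> tuple[float, float]:
    """Lowest mask pixel in UP's column."""
    col = int(round(UP[0]))
    col = min(max(col, 0), obj.mask.shape[1] - 1)
    rows = np.nonzero(obj.mask[:, col])[0]
    if len(rows) == 0:
        raise NoFishError("belly column empty")
    return float(UP[0]), float(rows.max())


def extract_roi(
    obj: FishObject,
    EP: tuple[float, float],
    UP: tuple[float, float],
    BP: tuple[float, float],
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Cut the ROI rectangle; returns (gray crop, (x0, x1, y0, y1)).

    Bounds follow the landmark formula with floor on the top/left edge
    and ceil on the bottom/right edge.
    """
    y_top = UP[1] + (BP[1] - UP[1]) / 20.0
    y_bot = BP[1] / 2.0
    if y_bot <= y_top:
        raise DegenerateROIError("degenerate ROI: BP.y/2 above the top bound")
    x0 = int(np.floor(EP[0]))
    x1 = int(np.ceil(UP[0]))
    y0 = int(np.floor(y_top))
    y1 = int(np.ceil(y_bot))
    if x1 <= x0:
        raise DegenerateROIError("degenerate ROI: zero width")
    crop = obj.gray[y0:y1, x0:x1].copy()
    return crop, (x0, x1, y0, y1)


def normalize_roi(
    crop: np.ndarray,
    landmarks: Landmarks | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    width: int = ROI_WIDTH,
) -> NormalizedROI:
    """Resample the crop to the standard width, preserving aspect ratio."""
    h, w = crop.shape
    if w == 0 or h == 0:
        raise DegenerateROIError("empty ROI crop")
    out_h = max(int(round(h * width / w)), 1)
    if (w, h) == (width, out_h):
        img = crop.astype(float)
    else:
        img = resize(crop.astype(float), (out_h, width), order=1,
                     preserve_range=True, anti_aliasing=w > width)
    return NormalizedROI(
        image=img,
        landmarks=landmarks,
        origin=origin,
        scale=(width / w, out_h / h),
    )


def extract_normalized_roi(
    image: FishImage | np.ndarray, config: ROIConfig | None = None
) -> tuple[NormalizedROI, FishObject]:
    """Full chain: segment, de-skew, landmarks, ROI cut, normalization."""
    cfg = config or ROIConfig()
    bg = segment_background(image, cfg)
    obj = locate_fish(bg, image)
    obj.rgb = None  # landmarks and ROI need the gray crop only
    obj = deskew(obj, cfg.eye_threshold)
    np_col = find_narrowest(obj)
    obj.length_px = float(np_col)
    up = find_upper_fin(obj, obj.length_px)
    ep = find_eye(obj, up, cfg.eye_threshold)
    bp = find_belly(obj, up)
    lm = Landmarks(EP=ep, UP=up, BP=bp, NP=np_col)
    crop, (x0, _x1, y0, _y1) = extract_roi(obj, ep, up, bp)
    roi = normalize_roi(crop, landmarks=lm, origin=(float(x0), float(y0)),
                        width=cfg.roi_width)
    return roi, obj
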