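"""Shared fixtures: one small rendered cohort reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from finprint import detection, roi, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """6 fish x 3 images, one session, modest jitter; rendered lazily."""
    return synthetic.generate_cohort(6, 3, seed=11, image_jitter_sd=2.0)


@pytest.fixture(scope="session")
def cohort_products(small_cohort):
    """Rendered images run through ROI extraction and blob detection.

    Returns a list of dicts with the ROI, fish object, detected pattern
    and ground-truth dot positions projected into ROI coordinates.
    """
    out = []
    for i in range(len(small_cohort)):
        fi = small_cohort.render(i)
        nroi, obj = roi.extract_normalized_roi(fi)
        pat = detection.detect_dots_blob(nroi)
        pat.image_id, pat.fish_id, pat.session = (
            fi.image_id, fi.fish_id, fi.session)
        gt_roi = nroi.project(obj.to_object(fi.truth["dots_canvas"]))
        out.append({"image": fi, "roi": nroi, "obj": obj, "pattern": pat,
                    "gt_dots_roi": gt_roi, "fish_id": fi.fish_id})
    return out


@pytest.fixture(scope="session")
def patterns_by_fish(cohort_products):
    by_fish: dict = {}
    for rec in cohort_products:
        by_fish.setdefault(rec["fish_id"], []).append(rec["pattern"])
    return by_fish


@pytest.fixture(scope="session")
def trained_classifier():
    """Patch classifier trained on a reduced but fully separable set."""
    ds = synthetic.generate_patches(150, seed=2)
    clf, acc = detection.train_patch_classifier(ds, seed=0, epochs=20)
    return clf, acc, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
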