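"""Nucleus detection, density mapping, compartment classification, Ki67."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from pfahet import synth
from pfahet.density import (
    CompartmentMask,
    DensityMap,
    TissueImage,
    classify_compartments,
    density_map,
    detect_nuclei,
    ki67_fractions,
    tissue_mask_from_image,
)


def render_points(points_um, shape_px, scale, radius_um, flags=None):
    """Minimal independent renderer: Gaussian blobs at given positions."""
    img = np.zeros(shape_px)
    sigma = radius_um / 2 / scale
    for x, y in points_um:
        img[int(y / scale), int(x / scale)] += 1.0
    return gaussian_filter(img, sigma) * (2 * np.pi * sigma**2)


# -------------------------------------------------------------- detection ----

def test_blank_image_no_detections():
    img = TissueImage(np.zeros((100, 100)), 1.0)
    assert len(detect_nuclei(img)) == 0


def test_detection_of_500_planted_nonoverlapping_nuclei(rng):
    """>= 95% of 500 well-separated nuclei matched within one radius."""
    scale, radius = 1.0, 3.0
    grid = np.stack(np.meshgrid(np.arange(25), np.arange(20)), -1).reshape(-1, 2)
    pts = grid * 40.0 + 20.0 + rng.uniform(-5, 5, size=(500, 2))  # >= 20 µm apart
    img = TissueImage(render_points(pts, (820, 1020), scale, radius), scale)
    det = detect_nuclei(img, radius_um=radius)
    tree = cKDTree(pts)
    d, idx = tree.query(det[["x_um", "y_um"]].to_numpy(), k=1)
    matched = np.unique(idx[d <= radius])
    assert len(matched) >= 475
    assert (d <= radius).mean() >= 0.95  # precision


def test_detection_deterministic(tissue_03):
    img = TissueImage(tissue_03.image, tissue_03.scale_um_per_px)
    a = detect_nuclei(img)
    b = detect_nuclei(img)
    pd.testing.assert_frame_equal(a, b)


def test_detection_ki67_flags_recovered(rng):
    scale, radius = 1.0, 3.0
    pts = np.stack(np.meshgrid(np.arange(10), np.arange(10)), -1).reshape(-1, 2) * 40.0 + 20.0
    flags = np.arange(100) % 2 == 0
    primary = render_points(pts, (420, 420), scale, radius)
    ki = render_points(pts[flags], (420, 420), scale, radius)
    det = detect_nuclei(TissueImage(primary, scale, ki67=ki), radius_um=radius)
    tree = cKDTree(pts)
    _, idx = tree.query(det[["x_um", "y_um"]].to_numpy(), k=1)
    agree = det["ki67_positive"].to_numpy() == flags[idx]
    assert agree.mean() >= 0.95


def test_detection_without_ki67_channel_has_no_flags(tissue_03):
    img = TissueImage(tissue_03.image, tissue_03.scale_um_per_px)
    assert "ki67_positive" not in detect_nuclei(img).columns


# ------------------------------------------------------------ density map ----

def test_single_nucleus_density_closed_form():
    """One nucleus, 50 µm disc: 1000 / (pi * 50^2) ~ 0.127 cells/1,000 µm²."""
    nuc = pd.DataFrame({"x_um": [500.0], "y_um": [500.0]})
    dmap = density_map(nuc, (1000.0, 1000.0), grid_um=28.88, radius_um=50.0)
    xs, ys = dmap.grid_centers()
    j = np.argmin(np.abs(xs - 500))
    i = np.argmin(np.abs(ys - 500))
    assert dmap.values[i, j] == pytest.approx(1000 / (np.pi * 50**2), rel=1e-9)


def test_density_empty_no_nuclei_all_zero():
    dmap = density_map(pd.DataFrame({"x_um": [], "y_um": []}), (500.0, 500.0))
    assert not dmap.values.any()


def test_density_uniform_poisson_field(rng):
    """Intensity 10/1,000 µm²: the grid mean sits within 3 SD of 10."""
    lam = 10 / 1000
    w = h = 2000.0
    n = rng.poisson(lam * w * h)
    nuc = pd.DataFrame({"x_um": rng.uniform(0, w, n), "y_um": rng.uniform(0, h, n)})
    dmap = density_map(nuc, (w, h), radius_um=50.0)
    # grid points are correlated; bound with the field-level count SD
    se = 10 / np.sqrt(n)
    assert abs(dmap.values.mean() - 10) < 3 * se * 3


def test_density_edge_clipping_unbiased():
    """A nucleus at the corner still reports an unbiased local density:
    the disc area is clipped to the quarter inside the field."""
    nuc = pd.DataFrame({"x_um": [10.0], "y_um": [10.0]})
    dmap = density_map(nuc, (1000.0, 1000.0), grid_um=28.88, radius_um=50.0)
    corner = dmap.values[0, 0]
    assert corner > 1000 / (np.pi * 50**2)  # smaller denominator than a full disc


def test_density_integrates_to_count(tissue_03):
    """Sum of density x cell area / 1000 approximates the nucleus count."""
    nuc = tissue_03.nuclei
    dmap = density_map(nuc, (2000.0, 2000.0), radius_um=50.0)
    est = dmap.values.sum() * dmap.grid_um**2 / 1000.0
    assert est == pytest.approx(len(nuc), rel=0.05)


def test_density_zero_extent_errors():
    with pytest.raises(ValueError):
        density_map(pd.DataFrame({"x_um": [], "y_um": []}), (0.0, 100.0))


def test_density_radius_below_spacing_errors():
    with pytest.raises(ValueError):
        density_map(pd.DataFrame({"x_um": [], "y_um": []}), (100.0, 100.0), grid_um=30, radius_um=10)


# ------------------------------------------------------------ compartments ----

def _uniform_map(value, shape=(10, 10)):
    return DensityMap(np.full(shape, float(value)), 28.88, 50.0, (288.8, 288.8))


def test_uniform_density_above_threshold_all_dense():
    cm = classify_compartments(_uniform_map(12.0))
    assert cm.dense_fraction == 1.0


def test_density_exactly_at_threshold_is_sparse():
    """'More than 8.5' is strict: the boundary value classifies sparse."""
    cm = classify_compartments(_uniform_map(8.5))
    assert cm.dense_fraction == 0.0


def test_threshold_monotonicity(tissue_03_detected):
    _, _, dmap, _ = tissue_03_detected
    fracs = [classify_compartments(dmap, threshold=t).dense_fraction for t in (5.0, 8.5, 12.0)]
    assert fracs[0] >= fracs[1] >= fracs[2]


def test_empty_tissue_mask_errors():
    with pytest.raises(ValueError):
        classify_compartments(_uniform_map(12.0), tissue_mask=np.zeros((10, 10), bool))


def test_planted_nodule_fraction_recovered(tissue_03, tissue_03_detected):
    _, _, _, cmask = tissue_03_detected
    assert cmask.dense_fraction == pytest.approx(tissue_03.nodule_fraction_realized, abs=0.03)


def test_tissue_mask_covers_synthetic_field(tissue_03):
    img = TissueImage(tissue_03.image, tissue_03.scale_um_per_px)
    mask = tissue_mask_from_image(img)
    assert mask.mean() > 0.95


# ------------------------------------------------------------------- Ki67 ----

def test_ki67_all_positive_both_one():
    cm = CompartmentMask(
        dense=np.array([[True, False]]), tissue=np.ones((1, 2), bool),
        dense_fraction=0.5, grid_um=10.0,
    )
    nuc = pd.DataFrame(
        {"x_um": [2.0, 12.0], "y_um": [5.0, 5.0], "ki67_positive": [True, True]}
    )
    s = ki67_fractions(nuc, cm)
    assert s.ki67_fraction_dense == 1.0
    assert s.ki67_fraction_sparse == 1.0


def test_ki67_empty_compartment_undefined():
    cm = CompartmentMask(
        dense=np.array([[True, False]]), tissue=np.ones((1, 2), bool),
        dense_fraction=0.5, grid_um=10.0,
    )
    nuc = pd.DataFrame({"x_um": [2.0], "y_um": [5.0], "ki67_positive": [False]})
    s = ki67_fractions(nuc, cm)
    assert np.isnan(s.ki67_fraction_sparse)
    assert s.n_nuclei_sparse == 0


def test_ki67_missing_flags_errors(tissue_03_detected):
    _, _, _, cmask = tissue_03_detected
    with pytest.raises(ValueError, match="Ki67"):
        ki67_fractions(pd.DataFrame({"x_um": [1.0], "y_um": [1.0]}), cmask)


def test_ki67_rates_recovered_within_binomial_ci(tissue_03, tissue_03_detected):
    """Planted rates 0.30 (dense) / 0.05 (sparse) recovered within the
    binomial 99% CI given the per-compartment nucleus counts."""
    from scipy.stats import binom

    _, nuclei, _, cmask = tissue_03_detected
    s = ki67_fractions(nuclei, cmask, boundary_margin_cells=1)
    for rate, frac, n in [
        (0.30, s.ki67_fraction_dense, s.n_nuclei_dense),
        (0.05, s.ki67_fraction_sparse, s.n_nuclei_sparse),
    ]:
        assert n >= 300
        lo, hi = binom.ppf([0.005, 0.995], n, rate) / n
        # small extra margin: residual detection-merge flag error at this n
        assert lo - 0.015 <= frac <= hi + 0.015
    assert s.ki67_fraction_dense > s.ki67_fraction_sparse
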