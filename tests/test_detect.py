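"""Puncta detection: maxima prominence, segmentation, size filtering."""

import math

import numpy as np
import pytest
from scipy import ndimage

from syncoloc import (ChannelImage, DetectionParams, count_fish_particles,
                      filter_puncta_by_size, find_maxima, median_filter_image,
                      measure_filter_effect, segment_puncta, SynthConfig)
from syncoloc.detect import detect_puncta
from syncoloc.pipeline import default_detection_params
from syncoloc.synthetic import generate_synapse_field, render_field

_S8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------- oracles

def median_filter_oracle(a, radius):
    """Per-pixel brute-force disc median with reflect padding."""
    a = np.asarray(a, dtype=float)
    pad = np.pad(a, radius, mode="symmetric")  # edge-repeating reflection
    offs = [(dr, dc) for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]
    out = np.empty_like(a)
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            vals = [pad[r + radius + dr, c + radius + dc] for dr, dc in offs]
            out[r, c] = np.median(vals)
    return out


def prominence_oracle(a):
    """Exhaustive flood-fill prominence of every local-max plateau.

    Returns a list of (centroid_row, centroid_col, value, prominence)
    where prominence is value minus the highest threshold at which the
    suprathreshold component containing the plateau holds a strictly
    higher pixel (inf when no such threshold exists).
    """
    a = np.asarray(a, dtype=float)
    out = []
    levels = np.unique(a)[::-1]
    vmin = a.min()
    for v in levels:
        if v == vmin:
            continue  # a plateau at the global minimum has no relief
        eq_labels, n_eq = ndimage.label(a == v, structure=_S8)
        for lab in range(1, n_eq + 1):
            rr, cc = np.nonzero(eq_labels == lab)
            # plateau is a local max iff no 8-neighbor is higher
            is_max = True
            for r, c in zip(rr, cc):
                r0, r1 = max(r - 1, 0), min(r + 2, a.shape[0])
                c0, c1 = max(c - 1, 0), min(c + 2, a.shape[1])
                if (a[r0:r1, c0:c1] > v).any():
                    is_max = False
                    break
            if not is_max:
                continue
            prom = math.inf
            for t in levels[levels <= v]:
                comp, _ = ndimage.label(a >= t, structure=_S8)
                mine = comp[rr[0], cc[0]]
                if (a[comp == mine] > v).any():
                    prom = v - t
                    break
            out.append((rr.mean(), cc.mean(), v, prom))
    return out


def _sorted_maxima(maxima):
    return sorted((round(m[0], 9), round(m[1], 9), m[2], m[3])
                  for m in maxima)


# ---------------------------------------------------------- median filter

def test_median_filter_constant_and_impulse():
    const = ChannelImage(np.full((16, 16), 7.0), 27)
    assert np.array_equal(median_filter_image(const, 2).pixels, const.pixels)
    imp = np.zeros((16, 16))
    imp[8, 8] = 100.0
    out = median_filter_image(ChannelImage(imp, 27), 2).pixels
    assert out.max() == 0.0


def test_median_filter_radius_zero_identity():
    rng = np.random.default_rng(0)
    a = rng.random((12, 12))
    assert np.array_equal(median_filter_image(ChannelImage(a, 27), 0).pixels,
                          a)


def test_median_filter_matches_bruteforce():
    rng = np.random.default_rng(3)
    a = rng.random((32, 32)) * 100
    got = median_filter_image(ChannelImage(a, 27), 2).pixels
    np.testing.assert_allclose(got, median_filter_oracle(a, 2))


def test_median_filter_never_shrinks_convex_spot():
    """Diameter of an isolated convex spot is non-decreasing under the
    radius-2 median filter, up to a single boundary-pixel quantum (the
    disc median of a radially decreasing profile sits marginally below
    the center value, which can peel one pixel off the threshold
    contour)."""
    cfg = SynthConfig(fov_shape=(64, 64), noise_sd=0.0, seed=0)
    from syncoloc.synthetic import render_channel
    img = render_channel(np.array([[860.0, 860.0]]), np.array([1000.0]), cfg)
    params = DetectionParams(min_intensity=160, noise_tolerance=10,
                             median_radius=0, min_area_um2=0.0,
                             max_area_um2=50.0)
    before = segment_puncta(img, find_maxima(img, params), params)
    filt = median_filter_image(img, 2)
    after = segment_puncta(filt, find_maxima(filt, params), params)
    d_before = before.puncta[0].equivalent_diameter_nm
    d_after = after.puncta[0].equivalent_diameter_nm
    one_px_quantum = 2e3 * (27.0 / 1000.0) ** 2 / (math.pi * d_before / 1e3)
    assert d_after >= d_before - 1.5 * one_px_quantum


# ------------------------------------------------------------ find_maxima

def test_find_maxima_blank_and_constant():
    img = ChannelImage(np.full((16, 16), 5.0), 27)
    assert find_maxima(img, DetectionParams(0)) == []


def test_find_maxima_single_spot_peak():
    from syncoloc.synthetic import render_channel
    cfg = SynthConfig(fov_shape=(32, 32), noise_sd=0.0, seed=0)
    img = render_channel(np.array([[430.0, 430.0]]), np.array([900.0]), cfg)
    ms = find_maxima(img, DetectionParams(min_intensity=200,
                                          noise_tolerance=100))
    assert len(ms) == 1
    r, c = ms[0].row, ms[0].col
    assert abs(r - 430 / 27) <= 0.51 and abs(c - 430 / 27) <= 0.51


def test_find_maxima_plateau_centroid():
    a = np.zeros((7, 7))
    a[3, 2:5] = 4.0
    ms = find_maxima(ChannelImage(a, 27), DetectionParams(0))
    assert len(ms) == 1
    assert (ms[0].row, ms[0].col) == (3.0, 3.0)
    assert ms[0].prominence == math.inf


def test_two_spot_prominence_flip():
    """Maxima count flips from 2 to 1 exactly at the oracle prominence of
    the lower peak."""
    a = np.zeros((9, 15))
    a[4, 3] = 100.0
    a[4, 11] = 80.0
    a[4, 4:11] = 30.0          # ridge connecting them; saddle at 30
    oracle = prominence_oracle(a)
    lower = [m for m in oracle if m[2] == 80.0][0]
    prom = lower[3]
    assert prom == 50.0
    img = ChannelImage(a, 27)
    below = find_maxima(img, DetectionParams(0, noise_tolerance=prom))
    above = find_maxima(img, DetectionParams(0,
                                             noise_tolerance=prom + 1e-9))
    assert len(below) == 2
    assert len(above) == 1


@pytest.mark.parametrize("kind", ["float", "int"])
def test_find_maxima_matches_exhaustive_oracle(kind):
    """Exact agreement with the flood-fill prominence oracle on random
    images (plateau-rich integer images and generic float images)."""
    rng = np.random.default_rng(12345)
    n_images = 50
    for _ in range(n_images):
        if kind == "float":
            a = rng.random((32, 32)) * 100
        else:
            a = rng.integers(0, 12, (32, 32)).astype(float)
        got = _sorted_maxima((m.row, m.col, m.value, m.prominence)
                             for m in find_maxima(ChannelImage(a, 27),
                                                  DetectionParams(0)))
        want = _sorted_maxima(prominence_oracle(a))
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g[0] == pytest.approx(w[0]) and g[1] == pytest.approx(w[1])
            assert g[2] == w[2]
            assert (g[3] == w[3] == math.inf) or g[3] == pytest.approx(w[3])


def test_find_maxima_intensity_window():
    a = np.zeros((9, 9))
    a[2, 2] = 50.0
    a[6, 6] = 150.0
    ms = find_maxima(ChannelImage(a, 27),
                     DetectionParams(min_intensity=40, max_intensity=100))
    assert len(ms) == 1 and ms[0].value == 50.0


# --------------------------------------------------------- segment_puncta

def test_segment_isolated_spot_equals_component():
    from syncoloc.synthetic import render_channel
    cfg = SynthConfig(fov_shape=(48, 48), noise_sd=0.0, seed=0)
    img = render_channel(np.array([[650.0, 650.0]]), np.array([1000.0]), cfg)
    params = DetectionParams(min_intensity=200, noise_tolerance=50,
                             min_area_um2=0.0, max_area_um2=50.0)
    ps = segment_puncta(img, find_maxima(img, params), params)
    assert len(ps) == 1
    comp, n = ndimage.label(img.pixels >= 200, structure=_S8)
    want = set(map(tuple, np.argwhere(comp == 1)))
    assert set(map(tuple, ps.puncta[0].mask)) == want


def test_segment_two_overlapping_spots_partition():
    from syncoloc.synthetic import render_channel
    cfg = SynthConfig(fov_shape=(48, 48), noise_sd=0.0, seed=0)
    pts = np.array([[540.0, 650.0], [756.0, 650.0]])
    img = render_channel(pts, np.array([1000.0, 900.0]), cfg)
    params = DetectionParams(min_intensity=200, noise_tolerance=20,
                             min_area_um2=0.0, max_area_um2=50.0)
    ps = segment_puncta(img, find_maxima(img, params), params)
    assert len(ps) == 2
    m1 = set(map(tuple, ps.puncta[0].mask))
    m2 = set(map(tuple, ps.puncta[1].mask))
    assert not (m1 & m2)
    supra = set(map(tuple, np.argwhere(img.pixels >= 200)))
    assert m1 | m2 == supra


def test_segment_blank_image_empty():
    img = ChannelImage(np.zeros((16, 16)), 27)
    params = DetectionParams(min_intensity=10)
    ps = segment_puncta(img, find_maxima(img, params), params)
    assert len(ps) == 0


# ------------------------------------------------------------ size filter

def test_size_filter_bounds():
    areas_px = {0.01: 14, 0.05: 69, 4.9: 6722, 5.1: 6996}
    # 27 nm pixels: one px = 7.29e-4 um^2; counts chosen to hit the areas
    masks = []
    maxima = []
    shape = (400, 400)
    r0 = 0
    for n_px in areas_px.values():
        cols = 80
        rows = int(np.ceil(n_px / cols))
        mask = [(r0 + r, c) for r in range(rows) for c in range(cols)][:n_px]
        masks.append(mask)
        maxima.append(mask[0])
        r0 += rows + 2
    from conftest import make_puncta_set
    ps = make_puncta_set(masks, maxima, shape=shape)
    got = filter_puncta_by_size(ps, 0.05, 5.0)
    kept = sorted(round(p.area_um2, 2) for p in got.puncta)
    assert kept == [0.05, 4.9]
    marker = filter_puncta_by_size(ps, 0.02, 5.0)
    assert 0.01 not in {round(p.area_um2, 2) for p in marker.puncta}


def test_size_filter_empty_input():
    from conftest import make_puncta_set
    ps = make_puncta_set([], [])
    assert len(filter_puncta_by_size(ps, 0.02, 5.0)) == 0


# ----------------------------------------------------- filter effect, FISH

def test_filter_effect_zero_when_identical():
    from conftest import make_puncta_set
    ps = make_puncta_set([[(0, 0), (0, 1)]], [(0, 0)])
    delta, (lo, hi) = measure_filter_effect(ps, ps)
    assert delta == 0.0 and lo == 0.0 and hi == 0.0


def test_filter_effect_empty_raises():
    from conftest import make_puncta_set
    ps = make_puncta_set([[(0, 0)]], [(0, 0)])
    empty = make_puncta_set([], [])
    with pytest.raises(ValueError):
        measure_filter_effect(ps, empty)


def test_filter_effect_matches_bruteforce_filter():
    """Diameter change equals a recomputation on brute-force-filtered
    pixels."""
    from syncoloc.synthetic import render_channel
    cfg = SynthConfig(fov_shape=(64, 64), noise_sd=0.0, seed=4)
    pts = np.array([[400.0, 400.0], [1200.0, 1100.0]])
    img = render_channel(pts, np.array([1000.0, 800.0]), cfg)
    params = DetectionParams(min_intensity=180, noise_tolerance=50,
                             median_radius=0, min_area_um2=0.0,
                             max_area_um2=50.0)
    before = segment_puncta(img, find_maxima(img, params), params)
    filt_pkg = median_filter_image(img, 2)
    filt_oracle = img.copy_with(median_filter_oracle(img.pixels, 2))
    after_pkg = segment_puncta(filt_pkg, find_maxima(filt_pkg, params),
                               params)
    after_orc = segment_puncta(filt_oracle, find_maxima(filt_oracle, params),
                               params)
    d_pkg, _ = measure_filter_effect(before, after_pkg, seed=1)
    d_orc, _ = measure_filter_effect(before, after_orc, seed=1)
    assert d_pkg == pytest.approx(d_orc)


def test_fish_particle_counts():
    img = np.zeros((64, 64))
    spots = [(10, 10), (10, 30), (30, 20), (50, 50)]
    for r, c in spots:
        img[r - 1:r + 2, c - 1:c + 2] = 100.0
    ch = ChannelImage(img, 27)
    roi_a = np.zeros((64, 64), bool)
    roi_a[:40, :40] = True          # holds 3 spots
    roi_b = np.zeros((64, 64), bool)
    roi_b[40:, 40:] = True          # holds 1 spot
    counts = count_fish_particles(ch, [roi_a, roi_b], blur_sigma=1.0,
                                  threshold=10.0)
    assert counts == [3, 1]
    blank = ChannelImage(np.zeros((64, 64)), 27)
    assert count_fish_particles(blank, [roi_a, roi_b], 1.0, 10.0) == [0, 0]
    assert count_fish_particles(ch, [], 1.0, 10.0) == []


# --------------------------------------------------- detection properties

def _match_recall(found_nm, true_nm, tol_nm):
    if len(true_nm) == 0:
        return 1.0, 0
    from scipy.spatial import cKDTree
    d, _ = cKDTree(found_nm).query(true_nm, k=1)
    recall = float((d <= tol_nm).mean())
    dd, _ = cKDTree(true_nm).query(found_nm, k=1)
    false_pos = int((dd > tol_nm).sum())
    return recall, false_pos


def test_noiseless_detection_recovers_truth():
    """On a noise-free rendered field, prominence detection finds >= 99%
    of true spots (within 2 px) with no false positives."""
    cfg = SynthConfig(noise_sd=0.0, seed=21)
    gt = generate_synapse_field(cfg)
    images = render_field(gt)
    params = DetectionParams(min_intensity=150, noise_tolerance=1.0,
                             median_radius=0, min_area_um2=0.0,
                             max_area_um2=50.0)
    for ch in ("pre", "post"):
        ms = find_maxima(images[ch], params)
        found = np.array([[m.col * 27.0, m.row * 27.0] for m in ms])
        recall, fp = _match_recall(found, gt.points[ch], tol_nm=2 * 27.0)
        assert recall >= 0.99
        assert fp == 0


def test_recall_degrades_monotonically_with_noise():
    from syncoloc.synthetic import render_channel
    cfg0 = SynthConfig(fov_shape=(256, 256), seed=33, noise_sd=0.0)
    gt = generate_synapse_field(cfg0)
    params = DetectionParams(min_intensity=160, noise_tolerance=150,
                             median_radius=2, min_area_um2=0.02,
                             max_area_um2=5.0)
    recalls, fps = [], []
    for noise in (0.0, 80.0, 200.0):
        per_seed, per_fp = [], []
        for render_seed in (7, 8, 9):
            cfg = SynthConfig(fov_shape=(256, 256), seed=33, noise_sd=noise)
            img = render_channel(gt.points["pre"], gt.amplitudes["pre"],
                                 cfg, seed=render_seed)
            ps = detect_puncta(img, params)
            recall, fp = _match_recall(ps.maxima_nm(), gt.points["pre"],
                                       3 * 27.0)
            per_seed.append(recall)
            per_fp.append(fp)
        recalls.append(float(np.mean(per_seed)))
        fps.append(float(np.mean(per_fp)))
    assert recalls[0] >= recalls[1] >= recalls[2]
    assert fps[0] <= fps[1] <= fps[2]       # degradation shows up as FPs
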