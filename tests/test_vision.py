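"""Observer model: Weber fractions, RNL distances, blur, ranked filter, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcpattern.vision import (ConeCatchImage, InvalidInputError,
                              InvalidParameterError, VisualSystem, acuity_blur,
                              chromatic_delta_s, luminance_delta,
                              resolvable_extent_mm, rnl_cluster,
                              rnl_ranked_filter, weber_fractions)

positive = st.floats(0.05, 20.0, allow_nan=False)


# ---------------------------------------------------------------------------
# Weber fractions

@pytest.mark.parametrize("abundances,noise,expected", [
    ((1, 2, 2, 2), 0.05, (0.0707107, 0.05, 0.05, 0.05)),   # triggerfish values
    ((1, 1, 1, 1), 0.1, (0.1, 0.1, 0.1, 0.1)),
    ((1, 4, 4, 4), 0.05, (0.10, 0.05, 0.05, 0.05)),
])
def test_weber_fractions_closed_form(abundances, noise, expected):
    np.testing.assert_allclose(weber_fractions(abundances, noise), expected,
                               atol=1e-6)


def test_weber_fractions_printed_rounding():
    w = weber_fractions((1, 2, 2, 2), 0.05)
    assert tuple(np.round(w, 2)) == (0.07, 0.05, 0.05, 0.05)


@given(st.tuples(positive, positive, positive, positive), positive,
       st.floats(0.1, 10))
@settings(max_examples=50, deadline=None)
def test_weber_fractions_scale_invariant(ab, noise, c):
    np.testing.assert_allclose(weber_fractions(np.array(ab) * c, noise),
                               weber_fractions(ab, noise), rtol=1e-10)


def test_weber_fractions_rejects_nonpositive():
    with pytest.raises(InvalidParameterError):
        weber_fractions((1, 0, 1, 1), 0.05)
    with pytest.raises(InvalidParameterError):
        weber_fractions((1, 1, 1, 1), 0.0)


# ---------------------------------------------------------------------------
# RNL distances

W3 = (0.0707107, 0.05, 0.05)


def test_chromatic_delta_s_frozen_value():
    # independent hand evaluation of the closed form:
    # dS^2 = 0.0075 / 3.125e-5 = 240 -> dS = 15.4919 (with w1 = 0.05*sqrt(2))
    got = chromatic_delta_s((1, 1, 1), (1, 1, np.e), (0.05 * np.sqrt(2), 0.05, 0.05))
    assert got == pytest.approx(np.sqrt(240.0), rel=1e-12)
    assert got == pytest.approx(15.4919, abs=1e-4)


def test_luminance_delta_closed_form():
    assert luminance_delta(np.e, 1.0, 0.05) == pytest.approx(20.0, rel=1e-12)
    assert luminance_delta(2.0, 2.0, 0.05) == 0.0


@given(st.tuples(positive, positive, positive),
       st.tuples(positive, positive, positive), st.floats(0.2, 5.0))
@settings(max_examples=80, deadline=None)
def test_delta_s_symmetry_and_scale_invariance(qa, qb, c):
    qa, qb = np.array(qa), np.array(qb)
    d1 = chromatic_delta_s(qa, qb, W3)
    assert d1 == pytest.approx(chromatic_delta_s(qb, qa, W3), rel=1e-9)
    assert d1 == pytest.approx(chromatic_delta_s(c * qa, c * qb, W3), rel=1e-9)
    assert luminance_delta(qa[0], qb[0], 0.05) == pytest.approx(
        luminance_delta(qb[0], qa[0], 0.05), rel=1e-9)


def test_delta_s_zero_iff_equal_ratios():
    assert chromatic_delta_s((1, 2, 3), (2, 4, 6), W3) == pytest.approx(0, abs=1e-12)
    assert chromatic_delta_s((1, 2, 3), (1, 2, 4), W3) > 0


def test_zero_catch_is_an_error_not_an_epsilon():
    with pytest.raises(InvalidInputError):
        chromatic_delta_s((0, 1, 1), (1, 1, 1), W3)
    with pytest.raises(InvalidInputError):
        luminance_delta(0.0, 1.0, 0.05)


# ---------------------------------------------------------------------------
# acuity blur

def test_resolvable_extent_closed_form():
    # 2 * 100 mm * tan((1/6) degree) at 3 cycles/degree
    assert resolvable_extent_mm(3.0, 100.0) == pytest.approx(0.5818, abs=1e-4)


def test_blur_leaves_constant_channel_unchanged(two_patch):
    img = two_patch(0.0, 0.0)
    out = acuity_blur(img, 3.0, 500.0)
    np.testing.assert_allclose(out.catches[img.mask], img.catches[img.mask],
                               rtol=1e-9)
    assert np.array_equal(out.mask, img.mask)


def test_blur_reduces_high_frequency_energy_with_distance(two_patch):
    from scipy import ndimage
    rng = np.random.default_rng(0)
    img = two_patch(0.0, 6.0, shape=(24, 32))
    img.catches[img.mask] *= np.exp(rng.normal(0, 0.1, (img.mask.sum(), 4)))

    def hf_energy(im):
        return ndimage.laplace(im.catches[:, :, 3]).var()

    near = acuity_blur(img, 3.0, 200.0)
    far = acuity_blur(img, 3.0, 1000.0)
    assert hf_energy(far) < hf_energy(near) < hf_energy(img)


def test_blur_below_quarter_pixel_passes_through(two_patch, caplog):
    img = two_patch(1.0, 1.0)
    with caplog.at_level("WARNING"):
        out = acuity_blur(img, 3.0, 1.0)   # sigma << 0.25 px at 1 mm
    np.testing.assert_array_equal(out.catches, img.catches)
    assert any("passed through" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# ranked filter

def test_ranked_filter_uniform_image_unchanged(vs, base_catches):
    catches = np.ones((8, 8, 4)) * base_catches
    img = ConeCatchImage(catches, np.ones((8, 8), bool), 1.0)
    out = rnl_ranked_filter(img, vs, 3, 2, 2)
    np.testing.assert_allclose(out.catches[img.mask], img.catches[img.mask],
                               rtol=1e-9)


def test_ranked_filter_reduces_within_patch_variance(vs, two_patch):
    rng = np.random.default_rng(1)
    img = two_patch(3.0, 6.0, shape=(16, 24))
    noisy = img.catches * np.exp(rng.normal(0, 0.1, img.catches.shape))
    noisy[~img.mask] = 0
    img = ConeCatchImage(noisy, img.mask, img.px_per_mm)
    out = rnl_ranked_filter(img, vs, falloff=3, radius=5, repetitions=5)
    left = np.s_[:, :12]
    for c in range(4):
        assert out.catches[left + (c,)].var() < img.catches[left + (c,)].var()


def test_ranked_filter_parameter_validation(vs, two_patch):
    with pytest.raises(InvalidParameterError):
        rnl_ranked_filter(two_patch(1, 1), vs, 3, 0, 5)
    with pytest.raises(InvalidParameterError):
        rnl_ranked_filter(two_patch(1, 1), vs, 3, 5, 0)


# ---------------------------------------------------------------------------
# clustering

def test_cluster_uniform_image_single_cluster(vs, base_catches):
    catches = np.ones((6, 6, 4)) * base_catches
    img = ConeCatchImage(catches, np.ones((6, 6), bool), 1.0)
    cp = rnl_cluster(img, vs)
    assert cp.K == 1
    assert cp.cluster_abundance.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(cp.labels[img.mask] == 1)


@pytest.mark.parametrize("ds,dl,expected_k", [
    (1.5, 0.0, 1),   # chromatic separation below threshold merges
    (2.5, 0.0, 2),   # above the 2 dS colour threshold stays split
    (0.0, 5.0, 2),   # luminance criterion alone blocks the merge
    (0.0, 3.5, 1),
    (1.9, 3.9, 1),   # both below -> merge
])
def test_cluster_two_patch_thresholds(vs, two_patch, ds, dl, expected_k):
    assert rnl_cluster(two_patch(ds, dl), vs).K == expected_k


def test_cluster_output_respects_merge_invariant(vs, base_catches):
    """No two adjacent clusters may be below both thresholds (checked exhaustively)."""
    rng = np.random.default_rng(7)
    catches = np.ones((12, 12, 4)) * base_catches
    catches *= np.exp(rng.normal(0, 0.15, catches.shape))
    img = ConeCatchImage(catches, np.ones((12, 12), bool), 1.0)
    cp = rnl_cluster(img, vs)
    adj = set()
    for (dy, dx) in ((0, 1), (1, 0)):
        a = cp.labels[:, :-1] if dx else cp.labels[:-1, :]
        b = cp.labels[:, 1:] if dx else cp.labels[1:, :]
        for la, lb in zip(a.ravel(), b.ravel()):
            if la != lb and la > 0 and lb > 0:
                adj.add((min(la, lb), max(la, lb)))
    for la, lb in adj:
        qa, qb = cp.cluster_catches[la - 1], cp.cluster_catches[lb - 1]
        ds = chromatic_delta_s(qa[:3], qb[:3], vs.chrom_webers)
        dl = luminance_delta(qa[3], qb[3], vs.lum_weber)
        assert ds >= vs.chrom_threshold or dl >= vs.lum_threshold


def test_cluster_threshold_flip_location(vs, two_patch):
    """Sweeping the planted contrast locates the merge/split flip at the threshold."""
    step = 0.05
    sweep = np.arange(1.8, 2.2 + step / 2, step)
    ks = [rnl_cluster(two_patch(ds, 0.0), vs).K for ds in sweep]
    flip = sweep[next(i for i, k in enumerate(ks) if k == 2)]
    assert flip == pytest.approx(vs.chrom_threshold, abs=step)
    sweep_l = np.arange(3.8, 4.2 + step / 2, step)
    ks = [rnl_cluster(two_patch(0.0, dl), vs).K for dl in sweep_l]
    flip = sweep_l[next(i for i, k in enumerate(ks) if k == 2)]
    assert flip == pytest.approx(vs.lum_threshold, abs=step)


def test_degenerate_mask_rejected(base_catches):
    catches = np.ones((3, 3, 4)) * base_catches
    mask = np.zeros((3, 3), bool)
    mask[0, :2] = True
    with pytest.raises(InvalidInputError):
        ConeCatchImage(catches, mask, 1.0)
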