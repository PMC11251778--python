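"""Pattern statistics: registry contract, transition matrices, CAA/VCA/BSA/LEIA."""

import math

import numpy as np
import pytest

from qcpattern.metrics import (FAMILY_COUNTS, METRIC_REGISTRY, MetricVector,
                               TransitionMatrix, bsa_metrics, caa_metrics,
                               full_qcpa, leia_metrics, transition_matrices,
                               vca_metrics)
from qcpattern.synth import PatternRecipe, gen_image, solve_element_catches
from qcpattern.vision import ClusteredPattern, ConeCatchImage, rnl_cluster

from conftest import label_image


# ---------------------------------------------------------------------------
# oracle: exhaustive adjacency enumeration on tiny label maps

def brute_force_transitions(labels):
    """Count unordered label pairs over every 4-neighbour adjacency explicitly."""
    H, W = labels.shape
    hrz, vrt = {}, {}
    for y in range(H):
        for x in range(W):
            if labels[y, x] == 0:
                continue
            if x + 1 < W and labels[y, x + 1] > 0:
                k = tuple(sorted((labels[y, x], labels[y, x + 1])))
                hrz[k] = hrz.get(k, 0) + 1
            if y + 1 < H and labels[y + 1, x] > 0:
                k = tuple(sorted((labels[y, x], labels[y + 1, x])))
                vrt[k] = vrt.get(k, 0) + 1
    return hrz, vrt


def cp_from_labels(labels, catch_map, px_per_mm=1.0):
    labels = np.asarray(labels)
    K = labels.max()
    catches = np.stack([np.asarray(catch_map[k], float) for k in range(1, K + 1)])
    counts = np.array([(labels == k).sum() for k in range(1, K + 1)], float)
    return ClusteredPattern(labels, catches, counts / counts.sum(), px_per_mm)


Q1 = (0.1, 0.2, 0.3, 0.2)
Q2 = (0.3, 0.2, 0.1, 0.5)
Q3 = (0.2, 0.1, 0.2, 0.1)


def test_registry_size_and_family_allocation():
    assert len(METRIC_REGISTRY) == 157
    assert len(set(METRIC_REGISTRY)) == 157
    for fam, n in FAMILY_COUNTS.items():
        assert sum(1 for m in METRIC_REGISTRY if m.startswith(fam + ".")) == n


def test_transition_matrix_2x2_example():
    cp = cp_from_labels([[1, 1], [2, 2]], {1: Q1, 2: Q2})
    tms = transition_matrices(cp)
    assert tms["hrz"].counts[0, 0] == 1 and tms["hrz"].counts[1, 1] == 1
    assert tms["hrz"].counts[0, 1] == 0
    assert tms["vrt"].counts[0, 1] == 2 and tms["vrt"].counts[1, 0] == 2
    assert tms["full"].n_transitions == tms["hrz"].n_transitions + tms["vrt"].n_transitions


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_transition_matrices_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, size=(7, 8))
    K = 3
    cp = cp_from_labels(labels, {1: Q1, 2: Q2, 3: Q3}) if labels.max() == K else None
    if cp is None:
        labels[0, :3] = [1, 2, 3]
        cp = cp_from_labels(labels, {1: Q1, 2: Q2, 3: Q3})
    tms = transition_matrices(cp)
    for key, oracle in zip(("hrz", "vrt"), brute_force_transitions(cp.labels)):
        got = tms[key].counts
        for (a, b), n in oracle.items():
            assert got[a - 1, b - 1] == n
        assert tms[key].n_transitions == sum(oracle.values())
        assert np.array_equal(got, got.T)


# ---------------------------------------------------------------------------
# CAA

def test_caa_uniform_pattern():
    cp = cp_from_labels(np.ones((5, 5), int), {1: Q1})
    out = caa_metrics(cp, transition_matrices(cp))
    assert out["CAA.Sc"] == 1
    assert out["CAA.Qc"] == pytest.approx(1.0)
    for stat in ("C", "Qt", "Pt", "St", "Jt"):
        assert math.isnan(out[f"CAA.{stat}"])
    assert math.isnan(out["CAA.Asp"])


def test_caa_checkerboard_even_single_boundary_type():
    labels = np.indices((6, 6)).sum(axis=0) % 2 + 1
    cp = cp_from_labels(labels, {1: Q1, 2: Q2})
    out = caa_metrics(cp, transition_matrices(cp))
    assert out["CAA.Qt"] == pytest.approx(1.0)     # one boundary type, even
    assert out["CAA.Asp"] == pytest.approx(1.0)    # isotropic adjacencies
    assert out["CAA.St"] == 1


def test_caa_horizontal_stripes_aspect_and_run_length():
    # stripes of height 4 with one ragged column so horizontal transitions exist
    labels = np.zeros((16, 8), int)
    for y in range(16):
        labels[y, :] = (y // 4) % 2 + 1
    labels[3, 0] = 2  # notch
    cp = cp_from_labels(labels, {1: Q1, 2: Q2})
    out = caa_metrics(cp, transition_matrices(cp))
    assert out["CAA.Asp"] > 1            # stripes transition along the body axis
    assert out["CAA.Pt.Vrt"] == pytest.approx(4.0, rel=0.1)


def test_caa_against_brute_force_oracle():
    """Entropy/evenness statistics recomputed explicitly from enumerated adjacencies."""
    rng = np.random.default_rng(3)
    labels = rng.integers(1, 4, size=(8, 8))
    cp = cp_from_labels(labels, {1: Q1, 2: Q2, 3: Q3})
    out = caa_metrics(cp, transition_matrices(cp))
    hrz, vrt = brute_force_transitions(labels)
    full = dict(hrz)
    for k, v in vrt.items():
        full[k] = full.get(k, 0) + v
    off = np.array([v for (a, b), v in full.items() if a != b], float)
    t = off / off.sum()
    assert out["CAA.C"] == pytest.approx(np.exp(-np.sum(t * np.log(t))), rel=1e-9)
    assert out["CAA.St"] == len(off)
    assert out["CAA.Qt"] == pytest.approx((1 / np.sum(t ** 2)) / len(off), rel=1e-9)
    diag = np.array([full.get((k, k), 0) for k in (1, 2, 3)], float)
    d = diag / diag.sum()
    assert out["CAA.Qc"] == pytest.approx((1 / np.sum(d ** 2)) / 3, rel=1e-9)
    n_off_h = sum(v for (a, b), v in hrz.items() if a != b)
    n_off_v = sum(v for (a, b), v in vrt.items() if a != b)
    assert out["CAA.Asp"] == pytest.approx(n_off_v / n_off_h, rel=1e-9)


# ---------------------------------------------------------------------------
# VCA

def test_vca_two_cluster_weber_contrast(vs):
    labels = np.ones((4, 8), int)
    labels[:, 4:] = 2
    cp = cp_from_labels(labels, {1: (0.2, 0.2, 0.2, 1.0), 2: (0.2, 0.2, 0.2, 3.0)})
    out = vca_metrics(cp, vs, transition_matrices(cp))
    assert out["VCA.ML"] == pytest.approx(0.5)     # |1-3|/(1+3)
    assert out["VCA.sL"] == pytest.approx(0.0, abs=1e-12)
    assert out["VCA.MS"] == pytest.approx(0.0, abs=1e-9)   # identical chromatic
    assert out["VCA.MDmax"] == pytest.approx(0.0, abs=1e-9)
    assert out["VCA.MSL"] > 0


def test_vca_single_cluster_is_nan(vs):
    cp = cp_from_labels(np.ones((4, 4), int), {1: Q1})
    out = vca_metrics(cp, vs, transition_matrices(cp))
    assert all(math.isnan(v) for v in out.values())


def test_vca_bsa_scale_invariance(vs):
    rng = np.random.default_rng(5)
    labels = rng.integers(1, 4, size=(8, 8))
    cp1 = cp_from_labels(labels, {1: Q1, 2: Q2, 3: Q3})
    cp2 = ClusteredPattern(cp1.labels, cp1.cluster_catches * 7.3,
                           cp1.cluster_abundance, cp1.px_per_mm)
    tms = transition_matrices(cp1)
    for fn in (vca_metrics, bsa_metrics):
        a, b = fn(cp1, vs, tms), fn(cp2, vs, tms)
        for k in a:
            if math.isfinite(a[k]):
                assert a[k] == pytest.approx(b[k], rel=1e-9), k


# ---------------------------------------------------------------------------
# BSA

def test_bsa_boundary_weighted_mean_by_hand(vs):
    """Two boundary types with counts 3:1 and luminance contrasts (2, 6) -> 3.0."""
    w = vs.lum_weber
    qb = 0.2
    counts = np.zeros((3, 3), int)
    counts[0, 1] = counts[1, 0] = 3
    counts[0, 2] = counts[2, 0] = 1
    T = TransitionMatrix(counts, "full")
    cmap = {1: (qb, qb, qb, qb),
            2: (qb, qb, qb, qb * np.exp(2 * w)),    # dL = 2 to cluster 1
            3: (qb, qb, qb, qb * np.exp(-6 * w))}   # dL = 6 to cluster 1
    cp = cp_from_labels(np.array([[1, 2], [3, 1]]), cmap)
    out = bsa_metrics(cp, vs, {"full": T, "hrz": T, "vrt": T})
    assert out["BSA.BMSL"] == pytest.approx(0.75 * 2 + 0.25 * 6, rel=1e-9)


def test_bsa_single_boundary_type(vs):
    labels = np.ones((4, 6), int)
    labels[:, 3:] = 2
    cp = cp_from_labels(labels, {1: Q1, 2: Q2})
    out = bsa_metrics(cp, vs, transition_matrices(cp))
    assert out["BSA.BsSL"] == pytest.approx(0.0, abs=1e-12)
    assert out["BSA.BMSL"] == pytest.approx(out["BSA.BmaxSL"], rel=1e-12)


def test_bsa_directional_equals_full_on_isotropic_pattern(vs):
    labels = np.indices((8, 8)).sum(axis=0) % 2 + 1   # checkerboard
    cp = cp_from_labels(labels, {1: Q1, 2: Q2})
    out = bsa_metrics(cp, vs, transition_matrices(cp))
    assert out["BSA.BMSL.Vrt"] == pytest.approx(out["BSA.BMSL"], rel=1e-9)
    assert out["BSA.BMCS.Hrz"] == pytest.approx(out["BSA.BMCS"], rel=1e-9)


def test_directional_means_bracket_full_matrix_mean(vs):
    rng = np.random.default_rng(11)
    labels = rng.integers(1, 4, size=(10, 10))
    cp = cp_from_labels(labels, {1: Q1, 2: Q2, 3: Q3})
    tms = transition_matrices(cp)
    out = bsa_metrics(cp, vs, tms)
    for stat in ("BSA.BMSL", "BSA.BMCS", "BSA.BML"):
        lo = min(out[stat + ".Hrz"], out[stat + ".Vrt"])
        hi = max(out[stat + ".Hrz"], out[stat + ".Vrt"])
        assert lo - 1e-12 <= out[stat] <= hi + 1e-12


# ---------------------------------------------------------------------------
# LEIA

def test_leia_uniform_image_all_zero(vs, base_catches):
    img = label_image(np.ones((6, 6), int), {1: base_catches})
    out = leia_metrics(img, vs)
    for k, v in out.items():
        assert v == pytest.approx(0.0, abs=1e-12), k


def test_leia_vertical_step_edge_directionality(vs, base_catches):
    elem = solve_element_catches(base_catches, 0.0, 5.0, vs)
    labels = np.ones((6, 8), int)
    labels[:, 4:] = 2
    img = label_image(labels, {1: base_catches, 2: elem})
    out = leia_metrics(img, vs)
    assert out["LEIA.Lum.mean.Hrz"] > 0
    assert out["LEIA.Lum.mean.Vrt"] == pytest.approx(0.0, abs=1e-12)
    assert out["LEIA.Col.mean.Hrz"] == pytest.approx(0.0, abs=1e-9)


def test_leia_invariant_to_global_luminance_scaling(vs, base_catches):
    rng = np.random.default_rng(2)
    catches = np.ones((6, 6, 4)) * base_catches
    catches *= np.exp(rng.normal(0, 0.2, catches.shape))
    img = label_image(np.ones((6, 6), int), {1: (1, 1, 1, 1)})
    img.catches[:] = catches
    out1 = leia_metrics(img, vs)
    img.catches[:, :, 3] *= 2.0
    out2 = leia_metrics(img, vs)
    for k in out1:
        assert out1[k] == pytest.approx(out2[k], rel=1e-9), k


# ---------------------------------------------------------------------------
# full pipeline vector

def test_full_qcpa_emits_exactly_157_statistics(vs):
    img = gen_image(PatternRecipe(pattern="spots", regularity_jitter=1.0, seed=4), vs)
    mv = full_qcpa(img, vs, 20.0)
    assert tuple(mv.values.keys()) == METRIC_REGISTRY
    assert len(mv.values) == 157
    assert mv.valid


def test_full_qcpa_uniform_pattern_invalid(vs):
    img = gen_image(PatternRecipe(pattern="uniform", seed=4), vs)
    mv = full_qcpa(img, vs, 20.0)
    assert not mv.valid
    assert math.isnan(mv.values["CAA.Asp"])
    assert mv.values["CAA.Sc"] == 1


def test_full_qcpa_leia_contrast_shrinks_with_distance(vs):
    img = gen_image(PatternRecipe(pattern="spots", regularity_jitter=1.0,
                                  achro_contrast=8.0, px_per_mm=6.0, seed=9), vs)
    near = full_qcpa(img, vs, 20.0)
    far = full_qcpa(img, vs, 100.0)
    assert far.values["LEIA.Lum.mean"] <= near.values["LEIA.Lum.mean"] + 1e-9
    assert far.values["LEIA.Col.mean"] <= near.values["LEIA.Col.mean"] + 1e-9


def test_metric_vector_rejects_wrong_names():
    with pytest.raises(Exception):
        MetricVector({"CAA.Sc": 1.0}, "x", 20.0, True)
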