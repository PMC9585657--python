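import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gliotex as g
from gliotex.features import (
    GLCM_DIRECTIONS,
    GLCM_FEATURE_NAMES,
    ExtractionConfig,
    extract_slice_features,
    feature_names,
    first_order,
    glcm,
    glcm_feature_block,
    glcm_features,
    quantize_roi,
    shape_features,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: pair enumeration + definitional sums
# ---------------------------------------------------------------------------

def brute_glcm(levels, d, direction, ng):
    h, w = levels.shape
    counts = np.zeros((ng, ng))
    dy, dx = direction[0] * d, direction[1] * d
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w and levels[r, c] > 0 and levels[r2, c2] > 0:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                counts[levels[r2, c2] - 1, levels[r, c] - 1] += 1
    total = counts.sum()
    return None if total == 0 else counts / total


def brute_glcm_features(p):
    """All 20 features from their defining sums, in plain loops."""
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i][j]
            p_sum[i + j] += p[i][j]

    def s(expr):
        return sum(
            expr(i + 1, j + 1) * p[i][j] for i in range(ng) for j in range(ng)
        )

    def ent(q):
        return -sum(v * math.log2(v) for v in q if v > 0)

    da = sum(k * p_diff[k] for k in range(ng))
    autoc = s(lambda i, j: i * j)
    out = {
        "autocorrelation": autoc,
        "clusterProminence": s(lambda i, j: (i + j - 2 * mu) ** 4),
        "clusterShade": s(lambda i, j: (i + j - 2 * mu) ** 3),
        "clusterTendency": s(lambda i, j: (i + j - 2 * mu) ** 2),
        "contrast": s(lambda i, j: (i - j) ** 2),
        "correlation": 0.0 if var <= 0 else (autoc - mu * mu) / var,
        "dissimilarity": s(lambda i, j: abs(i - j)),
        "homogeneity": s(lambda i, j: 1.0 / (1 + abs(i - j))),
        "jointAverage": mu,
        "jointEnergy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "jointEntropy": ent([p[i][j] for i in range(ng) for j in range(ng)]),
        "idm": s(lambda i, j: 1.0 / (1 + (i - j) ** 2)),
        "diffEntropy": ent(p_diff),
        "diffVariance": sum((k - da) ** 2 * p_diff[k] for k in range(ng)),
        "idmn": s(lambda i, j: 1.0 / (1 + (i - j) ** 2 / ng**2)),
        "idn": s(lambda i, j: 1.0 / (1 + abs(i - j) / ng)),
        "inverseVariance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "sumEntropy": ent(p_sum),
        "sumSquares": var,
        "jointMax": max(p[i][j] for i in range(ng) for j in range(ng)),
    }
    return out


def test_glcm_hand_example_2x2():
    """Horizontal pairs of [[1,1],[1,2]]: p(1,1)=1/2, p(1,2)=p(2,1)=1/4."""
    p = glcm(np.array([[1, 1], [1, 2]]), 1, (0, 1), 2)
    np.testing.assert_allclose(p, [[0.5, 0.25], [0.25, 0.0]], atol=1e-15)
    f = glcm_features(p)
    assert abs(f["contrast"] - 0.5) < 1e-12
    assert abs(f["dissimilarity"] - 0.5) < 1e-12
    assert abs(f["jointEntropy"] - 1.5) < 1e-12
    assert abs(f["jointMax"] - 0.5) < 1e-12
    assert abs(f["jointEnergy"] - 0.375) < 1e-12
    assert abs(f["correlation"] - (-1.0 / 3.0)) < 1e-12


def test_glcm_against_brute_force_on_small_images():
    """Oracle equivalence on random integer images up to 6x6, all distances
    and directions, matrices and all 20 features to 1e-10."""
    rng = np.random.default_rng(7)
    n_checked = 0
    for _ in range(150):
        h, w = rng.integers(2, 7, size=2)
        ng = int(rng.integers(2, 7))
        lv = rng.integers(0, ng + 1, size=(h, w))  # 0 = outside ROI
        if not (lv > 0).any():
            continue
        for d in (1, 4):
            for dirn in GLCM_DIRECTIONS:
                ref = brute_glcm(lv, d, dirn, ng)
                got = glcm(lv, d, dirn, ng)
                assert (ref is None) == (got is None)
                if ref is None:
                    continue
                np.testing.assert_allclose(got, ref, atol=1e-12)
                ref_f = brute_glcm_features(ref)
                got_f = glcm_features(got)
                for name in GLCM_FEATURE_NAMES:
                    assert abs(got_f[name] - ref_f[name]) < 1e-10, name
                n_checked += 1
    assert n_checked > 300


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_glcm_is_normalized_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    ng = int(rng.integers(2, 9))
    lv = rng.integers(0, ng + 1, size=tuple(rng.integers(2, 10, 2)))
    for dirn in GLCM_DIRECTIONS:
        p = glcm(lv, 1, dirn, ng)
        if p is None:
            continue
        assert abs(p.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(p, p.T, atol=1e-15)
        assert (p >= 0).all()


def test_glcm_no_pairs_in_single_row_vertical():
    lv = np.array([[1, 2, 1, 2]])
    assert glcm(lv, 1, (1, 0), 2) is None


def test_uniform_glcm_energy_is_one_over_k():
    p = np.zeros((4, 4))
    cells = [(0, 0), (1, 1), (2, 3), (3, 2), (0, 1), (1, 0)]
    for i, j in cells:
        p[i, j] = 1 / len(cells)
    f = glcm_features(p)
    assert abs(f["jointEnergy"] - 1 / len(cells)) < 1e-12


def test_constant_roi_glcm_limits():
    lv = np.ones((5, 5), dtype=int)  # all mass on one diagonal cell
    p = glcm(lv, 1, (0, 1), 4)
    f = glcm_features(p)
    assert f["contrast"] == 0
    assert abs(f["homogeneity"] - 1) < 1e-12
    assert abs(f["jointMax"] - 1) < 1e-12
    assert f["correlation"] == 0  # degenerate, by convention


def test_direction_block_single_direction_equals_that_direction():
    lv = np.array([[1, 2, 1, 2, 1]])  # only horizontal pairs exist
    block = glcm_feature_block(lv, 1, 2)
    only = glcm_features(glcm(lv, 1, (0, 1), 2))
    for name in GLCM_FEATURE_NAMES:
        assert abs(block[name] - only[name]) < 1e-12


def test_direction_contrast_isotropy_on_random_fields():
    """On an isotropic uncorrelated field, per-direction contrast is within
    10% of its mean (averaged over 50 seeds). A *correlated* field shows
    higher diagonal contrast simply because the d=1 diagonal offset spans
    sqrt(2) pixels of physical distance, so the check uses a correlation
    length well below the pixel size."""
    per_dir = np.zeros(4)
    for seed in range(50):
        px, m = g.generate_tumor_slice(
            g.TextureParams(0.25, 1.0, 0.0), shape=(48, 48), seed=seed
        )
        q = quantize_roi(px, m, 16)
        for k, dirn in enumerate(GLCM_DIRECTIONS):
            per_dir[k] += glcm_features(glcm(q, 1, dirn, 16))["contrast"]
    per_dir /= 50
    assert np.abs(per_dir / per_dir.mean() - 1).max() < 0.10


def test_contrast_grows_with_lag_on_smooth_field():
    for seed in range(5):
        px, m = g.generate_tumor_slice(
            g.TextureParams(4.0, 1.0, 0.0), shape=(48, 48), seed=seed
        )
        q = quantize_roi(px, m, 32)
        c1 = glcm_feature_block(q, 1, 32)["contrast"]
        c4 = glcm_feature_block(q, 4, 32)["contrast"]
        assert c4 >= c1


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_examples():
    px = np.array([[0.0, 1.0], [2.0, 3.0]])
    m = np.ones((2, 2), bool)
    np.testing.assert_array_equal(quantize_roi(px, m, 4), [[1, 2], [3, 4]])
    const = quantize_roi(np.full((3, 3), 7.0), np.ones((3, 3), bool), 8)
    assert set(const.ravel()) == {1}


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_quantize_range_normalization(seed):
    rng = np.random.default_rng(seed)
    px = rng.normal(size=(6, 6))
    m = rng.random((6, 6)) > 0.3
    if not m.any():
        m[0, 0] = True
    ng = int(rng.integers(2, 65))
    q = quantize_roi(px, m, ng)
    vals = q[m]
    assert vals.min() >= 1 and vals.max() <= ng
    assert (q[~m] == 0).all()
    if px[m].max() > px[m].min():
        assert vals.min() == 1 and vals.max() == ng  # min/max hit end levels


def test_quantize_shift_invariance_of_glcm_features(rng):
    px, m = g.generate_tumor_slice(g.TextureParams(2.0, 1.0, 0.3), seed=5)
    f0 = glcm_feature_block(quantize_roi(px, m, 64), 1, 64)
    f1 = glcm_feature_block(quantize_roi(px + 500.0, m, 64), 1, 64)
    for name in GLCM_FEATURE_NAMES:
        assert abs(f0[name] - f1[name]) < 1e-9


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def test_first_order_hand_examples():
    f = first_order([2, 4, 4, 6])
    assert f["MEAN"] == 4
    assert abs(f["SD"] - math.sqrt(2)) < 1e-12
    assert abs(f["SKEWNESS"]) < 1e-12
    assert first_order([-1, 2, 4])["MPP"] == 3.0


def test_first_order_matches_direct_formulas(rng):
    x = rng.normal(3, 2, 500)
    f = first_order(x)
    assert abs(f["MEAN"] - x.mean()) < 1e-10
    assert abs(f["SD"] - x.std()) < 1e-10
    d = x - x.mean()
    assert abs(f["SKEWNESS"] - (d**3).mean() / x.std() ** 3) < 1e-10
    assert abs(f["KURTOSIS"] - ((d**4).mean() / x.var() ** 2 - 3)) < 1e-10


def test_first_order_kurtosis_normal_limit():
    x = np.random.default_rng(99).standard_normal(10_000)
    assert abs(first_order(x)["KURTOSIS"]) < 0.15


def test_first_order_constant_and_no_positive_pixels():
    f = first_order(np.full(20, 5.0))
    assert f["SD"] == 0 and f["ENTROPY"] == 0 and f["SKEWNESS"] == 0
    f = first_order(np.array([-3.0, -1.0, -2.0]))
    assert f["MPP"] == 0.0  # recorded as 0, not an error


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def test_shape_square():
    m = np.zeros((20, 20), bool)
    m[5:15, 5:15] = True
    s = shape_features(m, (1.0, 1.0))
    assert s["area"] == 100.0
    assert abs(s["elongation"] - 1.0) < 1e-12


def test_shape_digital_disk_sphericity():
    yy, xx = np.mgrid[:64, :64]
    m = (yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 20**2
    s = shape_features(m, (1.0, 1.0))
    assert 0.95 <= s["sphericity"] <= 1.02


def test_shape_thin_bar():
    m = np.zeros((5, 30), bool)
    m[2, 5:25] = True
    s = shape_features(m, (1.0, 1.0))
    assert s["elongation"] < 0.2
    assert s["shortAxis"] <= s["longAxis"]
    assert s["shortAxis"] > 0


def test_shape_respects_anisotropic_spacing():
    m = np.zeros((12, 12), bool)
    m[4:8, 4:8] = True  # 4x4 px square
    s = shape_features(m, (2.0, 1.0))  # rows are 2 mm tall
    assert s["area"] == 4 * 4 * 2.0
    assert s["elongation"] < 1.0  # taller than wide


def test_shape_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        shape_features(np.zeros((8, 8), bool), (1, 1))


# ---------------------------------------------------------------------------
# the assembled 82-vector
# ---------------------------------------------------------------------------

def test_feature_vector_has_82_canonical_names(textured_slice):
    px, m = textured_slice
    f = extract_slice_features(px, m, (1, 1), "T1C")
    names = feature_names("T1C")
    assert len(f) == 82
    assert list(f) == names
    assert sum(1 for n in names if n.split("_")[0] in
               ("MEAN", "SD", "MPP", "ENTROPY", "SKEWNESS", "KURTOSIS")) == 36
    assert "KURTOSIS_0_T1C" in f and "GLCM4_correlation_T1C" in f
    assert "SHAPE_sphericity_T1C" in f


def test_feature_names_match_study_grammar():
    t2 = feature_names("T2")
    assert "GLCM1_clusterShade_T2" in t2
    assert "GLCM1_idn_T2" in t2
    assert "GLCM1_sumEntropy_T2" in t2
    assert "MEAN_0_T2" in t2 and "MPP_0_T2" in t2


def test_translation_invariance(textured_slice):
    """Shifting image and mask together leaves all 82 features unchanged
    (ROI kept away from borders so filtering sees the same neighborhood)."""
    px, m = textured_slice
    big = np.full((96, 96), float(px[~m].mean()))
    bigm = np.zeros((96, 96), bool)
    big[8:72, 8:72] = px
    bigm[8:72, 8:72] = m
    f0 = extract_slice_features(big, bigm, (1, 1), "T1C")
    shifted = np.roll(np.roll(big, 5, axis=0), -3, axis=1)
    shiftedm = np.roll(np.roll(bigm, 5, axis=0), -3, axis=1)
    f1 = extract_slice_features(shifted, shiftedm, (1, 1), "T1C")
    for name, v in f0.items():
        assert abs(f1[name] - v) <= 1e-8 * max(1.0, abs(v)), name


def test_minimum_roi_size_enforced():
    px = np.zeros((32, 32))
    m = np.zeros((32, 32), bool)
    m[10:12, 10:12] = True  # 4 px < 16
    with pytest.raises(ValueError, match="below minimum"):
        extract_slice_features(px, m, (1, 1), "T1C")


def test_volume_extraction_82_per_slice_and_order_independent(small_cohort):
    p = small_cohort.patients[0]
    table = g.extract_feature_vector(p.volumes["T1C"], p.mask, "T1C")
    assert table.shape[1] == 83  # slice_index + 82
    assert len(table) >= 1
    # per-slice independence: each row equals its standalone extraction
    row = table.iloc[len(table) // 2]
    iz = int(row["slice_index"])
    ref = extract_slice_features(
        p.volumes["T1C"].voxels[iz], p.mask.voxels[iz], (1.0, 1.0), "T1C"
    )
    for name, v in ref.items():
        assert abs(row[name] - v) < 1e-9 * max(1.0, abs(v))


def test_extraction_config_validation():
    with pytest.raises(ValueError):
        ExtractionConfig(ng=0)
    with pytest.raises(ValueError):
        ExtractionConfig(glcm_distances=(0,))
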