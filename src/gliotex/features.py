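"""The 82-feature texture vector: first-order, GLCM and shape features.

Per sequence and per tumor-bearing slice the vector comprises:

* 36 first-order features — 6 statistics (mean, SD, mean of positive pixels,
  entropy, skewness, kurtosis) of the in-ROI pixel pool at each of the 6 SSF
  levels of the LoG filter bank;
* 20 gray-level co-occurrence matrix (GLCM) features at pixel distance 1 and
  20 at distance 4, computed on the unfiltered image after fixed-bin-number
  quantization of the ROI, averaged over the four in-plane directions;
* 6 shape features of the ROI contour.

Naming follows the ``STAT_SSF_SEQ`` / ``GLCM{d}_{name}_SEQ`` /
``SHAPE_{name}_SEQ`` grammar, e.g. ``KURTOSIS_2_T1C``, ``GLCM1_sumEntropy_T2``,
``SHAPE_area_T1C``.

Conventions (documented, configurable where it matters): SD and skewness use
population moments (the ROI is the whole population of tumor pixels);
kurtosis is excess kurtosis (normal → 0); entropy is Shannon entropy in bits
of a 64-bin histogram over the in-ROI min–max; GLCM quantization is Ng=64
equal-width levels over the in-ROI min–max; GLCMs are symmetric and features
are averaged over the non-empty directions.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from skimage import measure

from .io import ImageVolume, ROIMask, validate_pair
from .logfilter import DEFAULT_SIGMA_PER_SSF, SSF_LEVELS, log_filter_slice, log_filter_volume

logger = logging.getLogger(__name__)

FIRST_ORDER_STATS = ("MEAN", "SD", "MPP", "ENTROPY", "SKEWNESS", "KURTOSIS")

GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "clusterProminence",
    "clusterShade",
    "clusterTendency",
    "contrast",
    "correlation",
    "dissimilarity",
    "homogeneity",
    "jointAverage",
    "jointEnergy",
    "jointEntropy",
    "idm",
    "diffEntropy",
    "diffVariance",
    "idmn",
    "idn",
    "inverseVariance",
    "sumEntropy",
    "sumSquares",
    "jointMax",
)

SHAPE_FEATURE_NAMES = ("perimeter", "area", "elongation", "sphericity", "longAxis", "shortAxis")

#: in-plane directions as (drow, dcol) unit offsets, scaled by the distance
GLCM_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclasses.dataclass
class ExtractionConfig:
    """Tunable knobs of the feature extractor (defaults = study conditions)."""

    ssf_levels: tuple = SSF_LEVELS
    ng: int = 64
    glcm_distances: tuple = (1, 4)
    n_entropy_bins: int = 64
    min_roi_pixels: int = 16
    sigma_per_ssf: float = DEFAULT_SIGMA_PER_SSF
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.ng < 2:
            raise ValueError(f"ng must be >= 2, got {self.ng}")
        if self.min_roi_pixels < 2:
            raise ValueError("min_roi_pixels must be >= 2")
        if any(d < 1 for d in self.glcm_distances):
            raise ValueError("GLCM distances must be >= 1")


def feature_names(sequence_tag: str, config: ExtractionConfig | None = None) -> list[str]:
    """Canonical ordered names of the 82 features for one sequence."""
    cfg = config or ExtractionConfig()
    names = [
        f"{stat}_{ssf}_{sequence_tag}" for ssf in cfg.ssf_levels for stat in FIRST_ORDER_STATS
    ]
    for d in cfg.glcm_distances:
        names += [f"GLCM{d}_{name}_{sequence_tag}" for name in GLCM_FEATURE_NAMES]
    names += [f"SHAPE_{name}_{sequence_tag}" for name in SHAPE_FEATURE_NAMES]
    return names


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def first_order(pixels_in_roi: np.ndarray, n_bins: int = 64) -> dict[str, float]:
    """The six first-order statistics of a pooled pixel sample.

    mean; population SD; MPP (mean over strictly positive pixels, 0 when
    none); Shannon entropy in bits of an ``n_bins`` equal-width histogram
    over the sample min–max; population skewness; excess kurtosis. Skewness
    and kurtosis of a constant sample are reported as 0.
    """
    x = np.asarray(pixels_in_roi, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 pixels")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite pixel values")
    mean = float(x.mean())
    sd = float(x.std())
    pos = x[x > 0]
    if pos.size == 0:
        logger.warning("MPP: no positive pixels in ROI pool; recording 0")
        mpp = 0.0
    else:
        mpp = float(pos.mean())
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        # equal-width binning over [min, max]; the max falls in the top bin
        idx = ((x - lo) * (n_bins / (hi - lo))).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)
        p = np.bincount(idx, minlength=n_bins) / x.size
        entropy = float(_entropy_bits(p))
        # population central moments
        d = x - mean
        m2 = float((d**2).mean())
        m3 = float((d**3).mean())
        m4 = float((d**4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    else:  # constant sample: single occupied bin, moments degenerate
        entropy, skew, kurt = 0.0, 0.0, 0.0
    return {
        "MEAN": mean,
        "SD": sd,
        "MPP": mpp,
        "ENTROPY": entropy,
        "SKEWNESS": skew,
        "KURTOSIS": kurt,
    }


def _first_order_stack(X: np.ndarray, n_bins: int = 64) -> dict[str, np.ndarray]:
    """First-order statistics of several pixel pools at once, shape (L, n).

    Vectorized equivalent of :func:`first_order` applied to each row (the
    row is one SSF level's in-ROI pool); identical conventions.
    """
    X = np.asarray(X, dtype=np.float64)
    L, n = X.shape
    mean = X.mean(axis=1)
    d = X - mean[:, None]
    m2 = (d**2).mean(axis=1)
    m3 = (d**3).mean(axis=1)
    m4 = (d**4).mean(axis=1)
    sd = np.sqrt(m2)
    variable = m2 > 0
    skew = np.where(variable, m3 / np.where(variable, m2, 1.0) ** 1.5, 0.0)
    kurt = np.where(variable, m4 / np.where(variable, m2, 1.0) ** 2 - 3.0, 0.0)
    pos = X > 0
    n_pos = pos.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mpp = np.where(n_pos > 0, (X * pos).sum(axis=1) / np.maximum(n_pos, 1), 0.0)
    if (n_pos == 0).any():
        logger.warning("MPP: no positive pixels in ROI pool; recording 0")
    lo = X.min(axis=1)
    hi = X.max(axis=1)
    entropy = np.zeros(L)
    for k in range(L):
        if hi[k] > lo[k]:
            idx = ((X[k] - lo[k]) * (n_bins / (hi[k] - lo[k]))).astype(np.int64)
            np.clip(idx, 0, n_bins - 1, out=idx)
            p = np.bincount(idx, minlength=n_bins) / n
            entropy[k] = _entropy_bits(p)
    return {
        "MEAN": mean,
        "SD": sd,
        "MPP": mpp,
        "ENTROPY": entropy,
        "SKEWNESS": skew,
        "KURTOSIS": kurt,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def quantize_roi(slice_pixels: np.ndarray, mask: np.ndarray, ng: int = 64) -> np.ndarray:
    """Quantize in-ROI pixels to integer gray levels 1..Ng; 0 marks outside.

    Equal-width binning of the in-ROI ``[min, max]`` range into ``ng``
    levels; the maximum maps to level ``ng``; a constant ROI maps entirely
    to level 1.
    """
    pixels = np.asarray(slice_pixels, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if pixels.shape != m.shape:
        raise ValueError("pixel/mask shape mismatch")
    if not m.any():
        raise ValueError("empty ROI")
    vals = pixels[m]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities in ROI")
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(pixels.shape, dtype=np.int64)
    if hi > lo:
        q = np.floor((pixels[m] - lo) / (hi - lo) * ng).astype(np.int64) + 1
        np.clip(q, 1, ng, out=q)
        levels[m] = q
    else:
        levels[m] = 1
    return levels


def glcm(
    quantized: np.ndarray, distance: int, direction: tuple[int, int], ng: int
) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix for one offset.

    Counts level pairs ``(a, b)`` at offset ``direction * distance`` where
    both pixels lie inside the ROI (level > 0), accumulating each pair in
    both orders, then normalizes to sum 1. Returns ``None`` when no valid
    pair exists at this offset.
    """
    lv = np.asarray(quantized, dtype=np.int64)
    dy, dx = (int(direction[0]) * distance, int(direction[1]) * distance)
    h, w = lv.shape
    if abs(dy) >= h or abs(dx) >= w:
        return None
    # view a at (r, c), view b at (r + dy, c + dx)
    ay = slice(0, h - dy) if dy >= 0 else slice(-dy, h)
    by = slice(dy, h) if dy >= 0 else slice(0, h + dy)
    ax = slice(0, w - dx) if dx >= 0 else slice(-dx, w)
    bx = slice(dx, w) if dx >= 0 else slice(0, w + dx)
    a = lv[ay, ax]
    b = lv[by, bx]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return None
    ai = a[valid] - 1
    bi = b[valid] - 1
    counts = np.bincount(ai * ng + bi, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    counts = counts + counts.T  # symmetric accumulation
    return counts / counts.sum()


@lru_cache(maxsize=8)
def _glcm_weights(ng: int) -> np.ndarray:
    """Cached (ng*ng, 13) weight matrix for the linear GLCM reductions.

    Every feature that is a linear functional of p(i,j) — and the raw
    moments the polynomial cluster features expand into — becomes one
    column, so a GLCM stack reduces to a single matmul.
    """
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = i[:, None], i[None, :]
    diff = np.abs(ii - jj)
    dsq = (ii - jj) ** 2
    ipj = ii + jj
    cols = [
        (ii * jj),                      # 0 autocorrelation / correlation
        dsq,                            # 1 contrast (= sum k^2 p_diff)
        diff,                           # 2 dissimilarity (= sum k p_diff)
        1.0 / (1.0 + diff),             # 3 homogeneity (inverse difference)
        1.0 / (1.0 + dsq),              # 4 idm
        1.0 / (1.0 + dsq / ng**2),      # 5 idmn
        1.0 / (1.0 + diff / ng),        # 6 idn
        np.where(dsq > 0, 1.0 / np.where(dsq > 0, dsq, 1.0), 0.0),  # 7 invVariance
        ii * np.ones_like(jj),          # 8 mu (joint average)
        ii**2 * np.ones_like(jj),       # 9 second raw moment of the marginal
        ipj**2,                         # 10 \
        ipj**3,                         # 11  > cluster-feature raw moments
        ipj**4,                         # 12 /
    ]
    W = np.stack(cols, axis=-1).reshape(ng * ng, -1)
    W.setflags(write=False)
    return W


@lru_cache(maxsize=8)
def _glcm_diag_indices(ng: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat bincount indices for the p_{|i-j|} and p_{i+j} distributions."""
    i = np.arange(1, ng + 1)
    ii, jj = i[:, None], i[None, :]
    diff_idx = np.abs(ii - jj).ravel()        # 0..ng-1
    sum_idx = (ii + jj).ravel() - 2           # 0..2ng-2
    return diff_idx, sum_idx


def _entropy_bits(q: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits along the last axis, with 0*log(0) = 0."""
    # clipping keeps log finite; q == 0 contributes exactly 0 * log(tiny) = 0
    return -(q * np.log2(np.maximum(q, 1e-300))).sum(axis=-1)


def _glcm_features_stack(P: np.ndarray) -> dict[str, np.ndarray]:
    """The 20 features of a stack of GLCMs, shape (n, ng, ng), vectorized."""
    n, ng, _ = P.shape
    flat = np.ascontiguousarray(P.reshape(n, -1))
    M = flat @ _glcm_weights(ng)
    (autoc, contrast, dissim, homog, idm, idmn, idn, inv_var,
     mu, si2, sp2, sp3, sp4) = (M[:, k] for k in range(13))
    diff_idx, sum_idx = _glcm_diag_indices(ng)
    p_diff = np.stack([np.bincount(diff_idx, weights=f, minlength=ng) for f in flat])
    p_sum = np.stack(
        [np.bincount(sum_idx, weights=f, minlength=2 * ng - 1) for f in flat]
    )
    var = si2 - mu**2
    # cluster features are binomial expansions of sum((i+j-2mu)^k p)
    tendency = sp2 - 4 * mu**2
    shade = sp3 - 6 * mu * sp2 + 16 * mu**3
    prominence = sp4 - 8 * mu * sp3 + 24 * mu**2 * sp2 - 48 * mu**4
    correlation = np.where(var > 0, (autoc - mu**2) / np.where(var > 0, var, 1.0), 0.0)
    return {
        "autocorrelation": autoc,
        "clusterProminence": prominence,
        "clusterShade": shade,
        "clusterTendency": tendency,
        "contrast": contrast,
        "correlation": correlation,
        "dissimilarity": dissim,
        "homogeneity": homog,
        "jointAverage": mu,
        "jointEnergy": (flat**2).sum(axis=1),
        "jointEntropy": _entropy_bits(flat),
        "idm": idm,
        "diffEntropy": _entropy_bits(p_diff),
        "diffVariance": contrast - dissim**2,  # sum k^2 p_diff - (sum k p_diff)^2
        "idmn": idmn,
        "idn": idn,
        "inverseVariance": inv_var,
        "sumEntropy": _entropy_bits(p_sum),
        "sumSquares": var,
        "jointMax": flat.max(axis=1),
    }


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 20 named co-occurrence features of one normalized symmetric GLCM.

    Entropies are in bits with the ``0*log(0) = 0`` convention; the
    correlation of a degenerate (zero-variance) GLCM is reported as 0.
    """
    p = np.asarray(p, dtype=np.float64)
    stacked = _glcm_features_stack(p[None, :, :])
    return {name: float(stacked[name][0]) for name in GLCM_FEATURE_NAMES}


def glcm_feature_block(
    quantized: np.ndarray, distance: int, ng: int, directions: tuple = GLCM_DIRECTIONS
) -> dict[str, float]:
    """Direction-averaged GLCM features at one pixel distance.

    Features are computed per direction and averaged over the directions
    with at least one valid in-ROI pair. Raises if all directions are empty.
    """
    mats = [glcm(quantized, distance, d, ng) for d in directions]
    mats = [m for m in mats if m is not None]
    if not mats:
        raise ValueError(f"no valid pixel pairs at distance {distance} in any direction")
    stacked = _glcm_features_stack(np.stack(mats))
    return {name: float(stacked[name].mean()) for name in GLCM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def shape_features(
    mask_slice: np.ndarray, spacing_mm_inplane: tuple[float, float]
) -> dict[str, float]:
    """Geometry of a 2D ROI: perimeter, area, axes, elongation, sphericity.

    Area is the pixel count times the pixel area (mm^2); the perimeter is the
    total length of the sub-pixel iso-contour of the mask (mm). Long and
    short axes are the ellipse-equivalent diameters ``4*sqrt(lambda)`` from
    the eigenvalues of the second central moment matrix of the in-mask pixel
    centers, with the per-pixel square extent (s^2/12 per axis) added so a
    one-pixel-wide region has the width of its pixels rather than zero.
    Sphericity is the 2D isoperimetric ratio ``2*sqrt(pi*area)/perimeter``.
    """
    m = np.asarray(mask_slice, dtype=bool)
    if m.ndim != 2:
        raise ValueError("expected 2D mask slice")
    if not m.any():
        raise ValueError("empty mask")
    sy, sx = (float(s) for s in spacing_mm_inplane)
    area = float(m.sum()) * sy * sx

    # trace the 0.5 iso-contour; a 3-point moving average of the closed
    # polygon removes the marching-squares staircase bias (~6% overestimate
    # on a digital disk, ~1% after smoothing)
    padded = np.pad(m.astype(np.float64), 1)
    perimeter = 0.0
    for contour in measure.find_contours(padded, 0.5):
        pts = contour[:-1] if np.array_equal(contour[0], contour[-1]) else contour
        if len(pts) >= 3:
            pts = (np.roll(pts, 1, axis=0) + pts + np.roll(pts, -1, axis=0)) / 3.0
        closed = np.vstack([pts, pts[:1]])
        seg = np.diff(closed, axis=0) * np.array([sy, sx])
        perimeter += float(np.sqrt((seg**2).sum(axis=1)).sum())

    rows, cols = np.nonzero(m)
    coords = np.stack([rows * sy, cols * sx], axis=1)
    cov = np.cov(coords, rowvar=False, bias=True).reshape(2, 2)
    cov += np.diag([sy**2 / 12.0, sx**2 / 12.0])  # finite pixel extent
    evals = np.linalg.eigvalsh(cov)
    short_axis = 4.0 * float(np.sqrt(max(evals[0], 0.0)))
    long_axis = 4.0 * float(np.sqrt(max(evals[1], 0.0)))
    return {
        "perimeter": perimeter,
        "area": area,
        "elongation": short_axis / long_axis,
        "sphericity": 2.0 * np.sqrt(np.pi * area) / perimeter,
        "longAxis": long_axis,
        "shortAxis": short_axis,
    }


# ---------------------------------------------------------------------------
# per-slice assembly
# ---------------------------------------------------------------------------

def extract_slice_features(
    slice_pixels: np.ndarray,
    mask_slice: np.ndarray,
    spacing_mm_inplane: tuple[float, float],
    sequence_tag: str,
    config: ExtractionConfig | None = None,
    filter_bank: dict[int, np.ndarray] | None = None,
) -> dict[str, float]:
    """The 82 named features of one tumor-bearing slice of one sequence.

    ``filter_bank`` may carry precomputed SSF responses of this slice (as
    produced per volume by :func:`gliotex.logfilter.log_filter_volume`).
    """
    cfg = config or ExtractionConfig()
    m = np.asarray(mask_slice, dtype=bool)
    n_roi = int(m.sum())
    if n_roi < cfg.min_roi_pixels:
        raise ValueError(f"ROI has {n_roi} pixels, below minimum {cfg.min_roi_pixels}")
    out: dict[str, float] = {}
    pools = []
    for ssf in cfg.ssf_levels:
        if filter_bank is not None:
            filtered = filter_bank[ssf]
        else:
            filtered = log_filter_slice(
                slice_pixels,
                spacing_mm_inplane,
                ssf,
                cfg.sigma_per_ssf,
                cfg.truncate,
                allowed_levels=cfg.ssf_levels,
            )
        pools.append(filtered[m])
    stats6 = _first_order_stack(np.stack(pools), n_bins=cfg.n_entropy_bins)
    for k, ssf in enumerate(cfg.ssf_levels):
        for stat in FIRST_ORDER_STATS:
            out[f"{stat}_{ssf}_{sequence_tag}"] = float(stats6[stat][k])
    quantized = quantize_roi(slice_pixels, m, cfg.ng)  # unfiltered image only
    # all distances and directions go through one stacked feature evaluation
    mats: list[np.ndarray] = []
    spans: list[tuple[int, int]] = []
    for d in cfg.glcm_distances:
        ms = [glcm(quantized, d, dirn, cfg.ng) for dirn in GLCM_DIRECTIONS]
        ms = [p for p in ms if p is not None]
        if not ms:
            raise ValueError(f"no valid pixel pairs at distance {d} in any direction")
        spans.append((d, len(ms)))
        mats.extend(ms)
    stacked = _glcm_features_stack(np.stack(mats))
    pos = 0
    for d, cnt in spans:
        for name in GLCM_FEATURE_NAMES:
            out[f"GLCM{d}_{name}_{sequence_tag}"] = float(
                stacked[name][pos : pos + cnt].mean()
            )
        pos += cnt
    shp = shape_features(m, spacing_mm_inplane)
    for name in SHAPE_FEATURE_NAMES:
        out[f"SHAPE_{name}_{sequence_tag}"] = shp[name]
    return out


def extract_feature_vector(
    volume: ImageVolume,
    mask: ROIMask,
    sequence_tag: str | None = None,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Per-slice 82-feature vectors for every eligible tumor-bearing slice.

    Returns a DataFrame with ``slice_index`` plus the 82 canonically ordered
    feature columns; slices whose ROI falls below the minimum pixel count are
    skipped with a logged warning.
    """
    cfg = config or ExtractionConfig()
    validate_pair(volume, mask)
    tag = sequence_tag or volume.sequence_tag
    spacing_inplane = volume.spacing_mm[1:]
    bank = log_filter_volume(
        volume.voxels, spacing_inplane, cfg.ssf_levels, cfg.sigma_per_ssf, cfg.truncate
    )
    rows = []
    for iz in range(volume.n_slices):
        m = mask.voxels[iz]
        n_roi = int(m.sum())
        if n_roi == 0:
            continue
        if n_roi < cfg.min_roi_pixels:
            warnings.warn(
                f"slice {iz}: ROI {n_roi} px below minimum {cfg.min_roi_pixels}; skipped",
                stacklevel=2,
            )
            continue
        slice_bank = {ssf: resp[iz] for ssf, resp in bank.items()}
        try:
            feats = extract_slice_features(
                volume.voxels[iz], m, spacing_inplane, tag, cfg, filter_bank=slice_bank
            )
        except ValueError as exc:
            if "no valid pixel pairs" not in str(exc):
                raise
            warnings.warn(f"slice {iz}: {exc}; skipped", stacklevel=2)
            continue
        rows.append({"slice_index": iz, **feats})
    columns = ["slice_index"] + feature_names(tag, cfg)
    return pd.DataFrame(rows, columns=columns)
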