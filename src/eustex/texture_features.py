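"""The 105-feature, 9-category texture description of an ultrasound sub-image.

Categories and counts
---------------------
1. ``histogram``        first-order grey-level statistics              (10)
2. ``glcm``             Haralick co-occurrence statistics, d = 1 and 2 (32)
3. ``glrlm``            grey-level run-length statistics               (11)
4. ``glds``             grey-level difference statistics               (5)
5. ``wavelet_entropy``  Shannon entropy of subband coefficient energy  (10)
6. ``wavelet_std``      subband coefficient standard deviation         (10)
7. ``wavelet_energy``   subband mean squared coefficient               (10)
8. ``laws``             Laws 3x3 texture-energy measures               (9)
9. ``gradient``         gradient-magnitude statistics                  (8)

Matrix-based categories (2-4) operate on a min-max quantized copy of the
sub-image (64 grey levels by default); first-order and filter-based
categories operate on the raw 8-bit intensities. All logarithms are base 2
with the convention 0*log(0) = 0, and statistics of a zero-variance sample
(skewness, kurtosis, correlation) are defined as 0 so that degenerate images
yield finite features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .roi_imaging import QuantizedImage, SubImage, as_gray_image, quantize

_EPS = 1e-12

# Unit displacement per direction (0, 45, 90, 135 degrees), distance 1.
_DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

#: Wavelet subbands of a 3-level decomposition, finest first.
SUBBANDS: tuple[str, ...] = ("ch1", "cv1", "cd1", "ch2", "cv2", "cd2",
                             "ch3", "cv3", "cd3", "ca3")

_GLCM_STATS: tuple[str, ...] = (
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
    "dissimilarity", "autocorrelation", "max_probability",
)

_HIST_STATS: tuple[str, ...] = ("mean", "variance", "std", "skewness",
                                "kurtosis", "energy", "entropy", "range",
                                "p10", "p90")

_GLRLM_STATS: tuple[str, ...] = ("sre", "lre", "gln", "rln", "rp",
                                 "lgre", "hgre", "srlge", "srhge",
                                 "lrlge", "lrhge")

_GLDS_STATS: tuple[str, ...] = ("mean", "variance", "entropy", "asm", "contrast")

_LAWS_KERNELS_1D: dict[str, np.ndarray] = {
    "l3": np.array([1.0, 2.0, 1.0]),
    "e3": np.array([-1.0, 0.0, 1.0]),
    "s3": np.array([-1.0, 2.0, -1.0]),
}

_GRAD_STATS: tuple[str, ...] = ("mean", "std", "skewness", "kurtosis",
                                "energy", "entropy", "max", "edge_fraction")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature extractor.

    grey_levels
        Bins used for the co-occurrence, run-length and difference matrices.
    glcm_distances
        Pixel offsets of the co-occurrence matrices; each distance
        contributes its own 16 Haralick statistics.
    wavelet / wavelet_levels
        Family and depth of the 2-D discrete wavelet transform.
    """

    grey_levels: int = 64
    glcm_distances: tuple[int, ...] = (1, 2)
    wavelet: str = "db4"
    wavelet_levels: int = 3


def _feature_inventory(config: FeatureConfig) -> dict[str, str]:
    """Ordered feature-name -> category map."""
    inv: dict[str, str] = {}
    for s in _HIST_STATS:
        inv[f"hist_{s}"] = "histogram"
    for d in config.glcm_distances:
        for s in _GLCM_STATS:
            inv[f"glcm_d{d}_{s}"] = "glcm"
    for s in _GLRLM_STATS:
        inv[f"glrlm_{s}"] = "glrlm"
    for s in _GLDS_STATS:
        inv[f"glds_{s}"] = "glds"
    for sb in SUBBANDS:
        inv[f"wav_entropy_{sb}"] = "wavelet_entropy"
    for sb in SUBBANDS:
        inv[f"wav_std_{sb}"] = "wavelet_std"
    for sb in SUBBANDS:
        inv[f"wav_energy_{sb}"] = "wavelet_energy"
    for a in _LAWS_KERNELS_1D:
        for b in _LAWS_KERNELS_1D:
            inv[f"laws_{a}{b}"] = "laws"
    for s in _GRAD_STATS:
        inv[f"grad_{s}"] = "gradient"
    return inv


#: Canonical inventory under the default configuration: 105 names, 9 categories.
FEATURE_CATEGORIES: dict[str, str] = _feature_inventory(FeatureConfig())
FEATURE_NAMES: tuple[str, ...] = tuple(FEATURE_CATEGORIES)

#: The 16-feature subset reported as optimal by the reference clinical study
#: (5 categories), under this package's nomenclature: "invariant moment" =
#: inverse difference moment, "consistency" = angular second moment /
#: histogram energy, "absolute value" = dissimilarity.
REFERENCE_SELECTED_FEATURES: tuple[str, ...] = (
    "glcm_d1_contrast", "glcm_d1_idm", "glcm_d1_entropy",
    "glcm_d1_sum_entropy", "glcm_d1_difference_variance",
    "glcm_d1_difference_entropy", "glcm_d1_asm", "glcm_d1_dissimilarity",
    "glcm_d1_imc1",
    "hist_std", "hist_energy", "hist_entropy",
    "wav_entropy_cv2", "wav_entropy_cv1",
    "wav_std_ca3",
    "glds_variance",
)


def _xlog2x(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0 log 0 := 0."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy(p: np.ndarray) -> float:
    return float(-_xlog2x(np.asarray(p, dtype=float)).sum())


def _moments(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """mean, variance, std, skewness, excess kurtosis (population moments).

    Zero-variance samples get skewness and kurtosis 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    mean = float(x.mean())
    var = float(x.var())
    std = float(np.sqrt(var))
    if std < _EPS:
        return mean, var, std, 0.0, 0.0
    z = (x - mean) / std
    return mean, var, std, float((z ** 3).mean()), float((z ** 4).mean() - 3.0)


def _hist_energy_entropy(x: np.ndarray, bins: int = 256,
                         value_range: tuple[float, float] | None = None,
                         ) -> tuple[float, float]:
    """Energy sum(h^2) and entropy -sum(h log2 h) of a normalized histogram."""
    x = np.asarray(x, dtype=float).ravel()
    if value_range is None:
        value_range = (0.0, 255.0)
    if value_range[1] <= value_range[0]:
        # degenerate range: everything in one bin
        return 1.0, 0.0
    h, _ = np.histogram(x, bins=bins, range=value_range)
    p = h / h.sum()
    return float((p ** 2).sum()), _entropy(p)


# ---------------------------------------------------------------------------
# 1. First-order histogram statistics
# ---------------------------------------------------------------------------

def histogram_features(sub: SubImage | np.ndarray) -> dict[str, float]:
    """First-order statistics of the grey-level distribution.

    Moments are computed on the raw intensities; energy and entropy on the
    256-bin normalized histogram.
    """
    pixels = sub.pixels if isinstance(sub, SubImage) else as_gray_image(sub)
    x = pixels.astype(float)
    mean, var, std, skew, kurt = _moments(x)
    energy, entropy = _hist_energy_entropy(x)
    return {
        "hist_mean": mean,
        "hist_variance": var,
        "hist_std": std,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_energy": energy,
        "hist_entropy": entropy,
        "hist_range": float(x.max() - x.min()),
        "hist_p10": float(np.percentile(x, 10)),
        "hist_p90": float(np.percentile(x, 90)),
    }


# ---------------------------------------------------------------------------
# 2. Grey-level co-occurrence matrix (Haralick statistics)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Glcm:
    """Symmetric, normalized grey-level co-occurrence matrix.

    ``p[i, j]`` is the probability of observing levels ``(i, j)`` at the
    configured offset, averaged over the retained directions.
    """

    p: np.ndarray
    levels: int
    distance: int
    directions: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.levels, self.levels):
            raise ValueError("co-occurrence matrix shape mismatch")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("co-occurrence matrix must be symmetric")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("co-occurrence matrix must be normalized")
        object.__setattr__(self, "p", p)


def compute_glcm(q: QuantizedImage, distance: int = 1,
                 directions: Sequence[tuple[int, int]] | None = None) -> Glcm:
    """Co-occurrence matrix at offset ``distance``, averaged over directions.

    Each directional matrix counts ordered level pairs, is symmetrized by
    adding its transpose, and normalized; the returned matrix is the mean of
    the (by default four) directional matrices.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    arr, g = q.pixels, q.levels
    h, w = arr.shape
    if distance >= min(h, w):
        raise ValueError("distance must be smaller than both image dimensions")
    dirs = tuple(directions) if directions is not None else tuple(
        (dr * distance, dc * distance) for dr, dc in _DIRECTIONS)
    mats = []
    for dr, dc in dirs:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = arr[r0:r1, c0:c1].ravel()
        b = arr[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        counts = np.bincount(a * g + b, minlength=g * g).reshape(g, g)
        counts = counts + counts.T
        mats.append(counts / counts.sum())
    return Glcm(np.mean(mats, axis=0), levels=g, distance=distance,
                directions=dirs)


def glcm_features(m: Glcm) -> dict[str, float]:
    """The 16 Haralick statistics of a normalized co-occurrence matrix.

    Nomenclature follows the classic inventory: ASM (angular second moment,
    a.k.a. consistency/energy), inverse difference moment (homogeneity),
    dissimilarity (mean absolute level difference), and the two
    informational measures of correlation IMC1/IMC2.
    """
    p, g = m.p, m.levels
    i = np.arange(g, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)                       # marginal (symmetric: px == py)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    # p_{x+y}(k), k = i + j in [0, 2g-2]; p_{x-y}(k), k = |i - j| in [0, g-1]
    psum = np.zeros(2 * g - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), p.ravel())
    pdiff = np.zeros(g)
    np.add.at(pdiff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    ks = np.arange(2 * g - 1, dtype=float)
    kd = np.arange(g, dtype=float)

    asm = float((p ** 2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    autocorr = float((ii * jj * p).sum())
    correlation = 0.0 if sigma < _EPS else (autocorr - mu * mu) / (sigma * sigma)
    variance = float(((ii - mu) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((ks * psum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * psum).sum())
    sum_entropy = _entropy(psum)
    entropy = _entropy(p)
    diff_mean = float((kd * pdiff).sum())
    difference_variance = float(((kd - diff_mean) ** 2 * pdiff).sum())
    difference_entropy = _entropy(pdiff)

    # informational measures of correlation (all logs base 2)
    pxy = np.outer(px, px)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nzm = pxy > 0
    hxy2 = float(-(pxy[nzm] * np.log2(pxy[nzm])).sum())
    hx = _entropy(px)
    imc1 = 0.0 if hx < _EPS else (entropy - hxy1) / hx
    imc2 = float(np.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - entropy)))))

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "autocorrelation": autocorr,
        "max_probability": float(p.max()),
    }


# ---------------------------------------------------------------------------
# 3. Grey-level run-length matrix
# ---------------------------------------------------------------------------

def _runs_along(line: np.ndarray) -> Iterable[tuple[int, int]]:
    """(level, run_length) pairs of maximal constant runs in a 1-D line."""
    if line.size == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    for s, e in zip(starts, ends):
        yield int(line[s]), int(e - s)


def _glrlm_matrix(arr: np.ndarray, levels: int,
                  direction: tuple[int, int]) -> np.ndarray:
    """Run-length count matrix R[level, length-1] for one direction."""
    h, w = arr.shape
    maxlen = max(h, w)
    mat = np.zeros((levels, maxlen), dtype=float)
    dr, dc = direction
    if (dr, dc) == (0, 1):
        lines = [arr[r] for r in range(h)]
    elif (dr, dc) == (-1, 0) or (dr, dc) == (1, 0):
        lines = [arr[:, c] for c in range(w)]
    elif (dr, dc) == (-1, 1):        # anti-diagonals
        flipped = np.flipud(arr)
        lines = [np.diagonal(flipped, k) for k in range(-h + 1, w)]
    elif (dr, dc) == (-1, -1) or (dr, dc) == (1, 1):   # main diagonals
        lines = [np.diagonal(arr, k) for k in range(-h + 1, w)]
    else:
        raise ValueError(f"unsupported run direction {direction}")
    for line in lines:
        for level, length in _runs_along(np.asarray(line)):
            mat[level, length - 1] += 1
    return mat


def glrlm_features(q: QuantizedImage,
                   directions: Sequence[tuple[int, int]] | None = None,
                   ) -> dict[str, float]:
    """Run-length statistics from the direction-averaged run-length matrix.

    Grey levels are weighted as ``level + 1`` so the lowest bin carries a
    finite low-grey-level emphasis.
    """
    dirs = tuple(directions) if directions is not None else _DIRECTIONS
    mats = [_glrlm_matrix(q.pixels, q.levels, d) for d in dirs]
    r = np.mean(mats, axis=0)
    n_runs = r.sum()
    n_px = q.pixels.size
    lev = (np.arange(r.shape[0], dtype=float) + 1.0)[:, None]
    rl = (np.arange(r.shape[1], dtype=float) + 1.0)[None, :]
    return {
        "glrlm_sre": float((r / rl ** 2).sum() / n_runs),
        "glrlm_lre": float((r * rl ** 2).sum() / n_runs),
        "glrlm_gln": float((r.sum(axis=1) ** 2).sum() / n_runs),
        "glrlm_rln": float((r.sum(axis=0) ** 2).sum() / n_runs),
        "glrlm_rp": float(n_runs / n_px),
        "glrlm_lgre": float((r / lev ** 2).sum() / n_runs),
        "glrlm_hgre": float((r * lev ** 2).sum() / n_runs),
        "glrlm_srlge": float((r / (lev ** 2 * rl ** 2)).sum() / n_runs),
        "glrlm_srhge": float((r * lev ** 2 / rl ** 2).sum() / n_runs),
        "glrlm_lrlge": float((r * rl ** 2 / lev ** 2).sum() / n_runs),
        "glrlm_lrhge": float((r * (lev * rl) ** 2).sum() / n_runs),
    }


# ---------------------------------------------------------------------------
# 4. Grey-level difference statistics
# ---------------------------------------------------------------------------

def glds_features(q: QuantizedImage,
                  displacements: Sequence[tuple[int, int]] | None = None,
                  ) -> dict[str, float]:
    """Statistics of |level difference| pooled over the unit displacements."""
    dirs = tuple(displacements) if displacements is not None else _DIRECTIONS
    arr = q.pixels
    h, w = arr.shape
    diffs = []
    for dr, dc in dirs:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        diffs.append(np.abs(arr[r0:r1, c0:c1] -
                            arr[r0 + dr:r1 + dr, c0 + dc:c1 + dc]).ravel())
    d = np.concatenate(diffs)
    pk = np.bincount(d, minlength=q.levels).astype(float)
    pk /= pk.sum()
    k = np.arange(pk.size, dtype=float)
    mean = float((k * pk).sum())
    return {
        "glds_mean": mean,
        "glds_variance": float(((k - mean) ** 2 * pk).sum()),
        "glds_entropy": _entropy(pk),
        "glds_asm": float((pk ** 2).sum()),
        "glds_contrast": float((k ** 2 * pk).sum()),
    }


# ---------------------------------------------------------------------------
# 5-7. Wavelet subband statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveletPyramid:
    """Named subbands of a 3-level 2-D discrete wavelet transform."""

    subbands: Mapping[str, np.ndarray]
    wavelet: str = "db4"
    levels: int = 3
    _coeff_list: list = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = set(SUBBANDS) - set(self.subbands)
        if missing:
            raise ValueError(f"missing subbands: {sorted(missing)}")


def wavelet_decompose(sub: SubImage | np.ndarray,
                      wavelet: str = "db4", levels: int = 3) -> WaveletPyramid:
    """3-level 2-D DWT with symmetric boundary extension.

    Returns the 10 named subbands ``ch/cv/cd`` per level plus the coarsest
    approximation ``ca3``.
    """
    pixels = sub.pixels if isinstance(sub, SubImage) else as_gray_image(sub)
    if min(pixels.shape) < 8:
        raise ValueError("wavelet decomposition needs at least an 8x8 image")
    import warnings
    with warnings.catch_warnings():
        # small sub-images make the coarsest level boundary-dominated; that
        # is accepted for ROIs near the 8x8 minimum
        warnings.filterwarnings("ignore", message="Level value .* too high")
        coeffs = pywt.wavedec2(pixels.astype(float), wavelet, mode="symmetric",
                               level=levels)
    bands: dict[str, np.ndarray] = {f"ca{levels}": coeffs[0]}
    for k, (ch, cv, cd) in enumerate(coeffs[1:]):
        lvl = levels - k
        bands[f"ch{lvl}"], bands[f"cv{lvl}"], bands[f"cd{lvl}"] = ch, cv, cd
    return WaveletPyramid(bands, wavelet=wavelet, levels=levels,
                          _coeff_list=coeffs)


def reconstruct(p: WaveletPyramid) -> np.ndarray:
    """Inverse transform from all subbands (round-trip check)."""
    coeffs = p._coeff_list
    if coeffs is None:
        coeffs = [p.subbands[f"ca{p.levels}"]] + [
            (p.subbands[f"ch{l}"], p.subbands[f"cv{l}"], p.subbands[f"cd{l}"])
            for l in range(p.levels, 0, -1)]
    return pywt.waverec2(coeffs, p.wavelet, mode="symmetric")


def wavelet_features(p: WaveletPyramid) -> dict[str, float]:
    """Per-subband Shannon entropy of the normalized coefficient-energy
    distribution, coefficient standard deviation, and mean squared
    coefficient. An all-zero subband has entropy and std 0."""
    out: dict[str, float] = {}
    for sb in SUBBANDS:
        c = np.asarray(p.subbands[sb], dtype=float).ravel()
        e = c ** 2
        tot = e.sum()
        out[f"wav_entropy_{sb}"] = _entropy(e / tot) if tot > _EPS else 0.0
    for sb in SUBBANDS:
        out[f"wav_std_{sb}"] = float(np.asarray(p.subbands[sb]).std())
    for sb in SUBBANDS:
        c = np.asarray(p.subbands[sb], dtype=float)
        out[f"wav_energy_{sb}"] = float((c ** 2).mean())
    return out


# ---------------------------------------------------------------------------
# 8. Laws texture-energy measures
# ---------------------------------------------------------------------------

def laws_features(sub: SubImage | np.ndarray) -> dict[str, float]:
    """Mean absolute response to the nine 3x3 Laws masks (outer products of
    level L3, edge E3 and spot S3 kernels), normalized by the L3L3 response
    to remove the illumination scale."""
    pixels = sub.pixels if isinstance(sub, SubImage) else as_gray_image(sub)
    x = pixels.astype(float)
    responses: dict[str, float] = {}
    for a, ka in _LAWS_KERNELS_1D.items():
        for b, kb in _LAWS_KERNELS_1D.items():
            mask = np.outer(ka, kb)
            resp = signal.convolve2d(x, mask, mode="valid")
            responses[f"laws_{a}{b}"] = float(np.abs(resp).mean())
    denom = max(responses["laws_l3l3"], _EPS)
    return {name: val / denom for name, val in responses.items()}


# ---------------------------------------------------------------------------
# 9. Gradient-magnitude statistics
# ---------------------------------------------------------------------------

_SOBEL_COL = np.array([[-1.0, 0.0, 1.0],
                       [-2.0, 0.0, 2.0],
                       [-1.0, 0.0, 1.0]])


def gradient_magnitude(sub: SubImage | np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude on the valid interior."""
    pixels = sub.pixels if isinstance(sub, SubImage) else as_gray_image(sub)
    x = pixels.astype(float)
    gc = signal.convolve2d(x, _SOBEL_COL, mode="valid")
    gr = signal.convolve2d(x, _SOBEL_COL.T, mode="valid")
    return np.hypot(gr, gc)


def gradient_features(sub: SubImage | np.ndarray) -> dict[str, float]:
    """First-order statistics of the gradient-magnitude map, plus the
    fraction of pixels stronger than 10% of the maximum (edge fraction)."""
    mag = gradient_magnitude(sub)
    mean, _, std, skew, kurt = _moments(mag)
    mx = float(mag.max())
    energy, entropy = _hist_energy_entropy(mag, value_range=(0.0, mx))
    if mx < _EPS:
        return {f"grad_{s}": 0.0 for s in _GRAD_STATS} | {"grad_energy": 1.0}
    return {
        "grad_mean": mean,
        "grad_std": std,
        "grad_skewness": skew,
        "grad_kurtosis": kurt,
        "grad_energy": energy,
        "grad_entropy": entropy,
        "grad_max": mx,
        "grad_edge_fraction": float((mag > 0.1 * mx).mean()),
    }


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_all(sub: SubImage | np.ndarray,
                config: FeatureConfig = FeatureConfig()) -> pd.Series:
    """Full 105-value feature vector of one sub-image, in canonical order.

    Deterministic: identical inputs give bit-identical vectors. All values
    are finite, including on degenerate (constant) images.
    """
    pixels = sub.pixels if isinstance(sub, SubImage) else as_gray_image(sub)
    if min(pixels.shape) < 8:
        raise ValueError("sub-image must be at least 8x8")
    q = quantize(pixels, config.grey_levels)
    values: dict[str, float] = {}
    values.update(histogram_features(pixels))
    for d in config.glcm_distances:
        stats = glcm_features(compute_glcm(q, distance=d))
        values.update({f"glcm_d{d}_{s}": v for s, v in stats.items()})
    values.update(glrlm_features(q))
    values.update(glds_features(q))
    values.update(wavelet_features(
        wavelet_decompose(pixels, config.wavelet, config.wavelet_levels)))
    values.update(laws_features(pixels))
    values.update(gradient_features(pixels))

    inventory = _feature_inventory(config)
    vec = pd.Series({name: values[name] for name in inventory}, dtype=float)
    if not np.isfinite(vec.to_numpy()).all():
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise AssertionError(f"non-finite features: {bad}")
    return vec


def feature_table(images: Sequence[np.ndarray | SubImage],
                  labels: Sequence[int],
                  case_ids: Sequence[str] | None = None,
                  config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Labelled cohort feature matrix.

    Columns: ``case_id``, ``label`` (cancer = 1, pancreatitis = 0), then the
    feature columns in canonical order.
    """
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    if case_ids is None:
        case_ids = [f"case{i:04d}" for i in range(len(images))]
    rows = [extract_all(im, config) for im in images]
    df = pd.DataFrame(rows).reset_index(drop=True)
    df.insert(0, "label", np.asarray(labels, dtype=int))
    df.insert(0, "case_id", list(case_ids))
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a cohort table (everything but case_id/label)."""
    return [c for c in table.columns if c not in ("case_id", "label")]
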