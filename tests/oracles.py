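"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops / direct enumeration,
deliberately sharing no code with the package, so agreement is evidence
rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def brute_largest_rectangle(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Exhaustive max-area all-True rectangle, ties: height desc, r0, c0."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    # summed-area table for O(1) all-True checks
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    best, best_key = (0, 0, 0, 0), (-1, -1, 0, 0)
    for r0 in range(h):
        for r1 in range(r0 + 1, h + 1):
            hh = r1 - r0
            for c0 in range(w):
                for c1 in range(c0 + 1, w + 1):
                    ww = c1 - c0
                    filled = (sat[r1, c1] - sat[r0, c1]
                              - sat[r1, c0] + sat[r0, c0])
                    if filled == hh * ww:
                        key = (hh * ww, hh, -r0, -c0)
                        if key > best_key:
                            best_key, best = key, (r0, c0, hh, ww)
    return best


def brute_glcm(arr: np.ndarray, levels: int,
               offsets: list[tuple[int, int]]) -> np.ndarray:
    """Pairwise co-occurrence by explicit pixel loops."""
    h, w = arr.shape
    mats = []
    for dr, dc in offsets:
        counts = np.zeros((levels, levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[arr[r, c], arr[r2, c2]] += 1
        counts = counts + counts.T
        mats.append(counts / counts.sum())
    return np.mean(mats, axis=0)


def _h(p: float) -> float:
    return -p * math.log2(p) if p > 0 else 0.0


def brute_glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 16 co-occurrence statistics from their defining sums."""
    g = p.shape[0]
    px = [sum(p[i, j] for j in range(g)) for i in range(g)]
    mu = sum(i * px[i] for i in range(g))
    sigma = math.sqrt(sum((i - mu) ** 2 * px[i] for i in range(g)))

    psum = [0.0] * (2 * g - 1)
    pdiff = [0.0] * g
    for i in range(g):
        for j in range(g):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]

    asm = sum(p[i, j] ** 2 for i in range(g) for j in range(g))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(g) for j in range(g))
    autocorr = sum(i * j * p[i, j] for i in range(g) for j in range(g))
    corr = 0.0 if sigma < 1e-12 else (autocorr - mu * mu) / sigma ** 2
    variance = sum((i - mu) ** 2 * p[i, j] for i in range(g) for j in range(g))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    sa = sum(k * psum[k] for k in range(len(psum)))
    sv = sum((k - sa) ** 2 * psum[k] for k in range(len(psum)))
    se = sum(_h(v) for v in psum)
    ent = sum(_h(p[i, j]) for i in range(g) for j in range(g))
    dmean = sum(k * pdiff[k] for k in range(g))
    dvar = sum((k - dmean) ** 2 * pdiff[k] for k in range(g))
    dent = sum(_h(v) for v in pdiff)

    hxy1 = -sum(p[i, j] * math.log2(px[i] * px[j])
                for i in range(g) for j in range(g)
                if p[i, j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                for i in range(g) for j in range(g) if px[i] * px[j] > 0)
    hx = sum(_h(v) for v in px)
    imc1 = 0.0 if hx < 1e-12 else (ent - hxy1) / hx
    imc2 = math.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - ent))))

    return {
        "asm": asm, "contrast": contrast, "correlation": corr,
        "variance": variance, "idm": idm, "sum_average": sa,
        "sum_variance": sv, "sum_entropy": se, "entropy": ent,
        "difference_variance": dvar, "difference_entropy": dent,
        "imc1": imc1, "imc2": imc2,
        "dissimilarity": sum(abs(i - j) * p[i, j]
                             for i in range(g) for j in range(g)),
        "autocorrelation": autocorr,
        "max_probability": float(p.max()),
    }


def _lines(arr: np.ndarray, direction: tuple[int, int]) -> list[list[int]]:
    """Pixel sequences along a direction, by walking from every start pixel."""
    h, w = arr.shape
    dr, dc = direction
    starts = []
    for r in range(h):
        for c in range(w):
            rp, cp = r - dr, c - dc
            if not (0 <= rp < h and 0 <= cp < w):
                starts.append((r, c))
    lines = []
    for r, c in starts:
        line = []
        while 0 <= r < h and 0 <= c < w:
            line.append(int(arr[r, c]))
            r, c = r + dr, c + dc
        lines.append(line)
    return lines


def brute_glrlm(arr: np.ndarray, levels: int,
                directions: list[tuple[int, int]]) -> np.ndarray:
    """Run-length count matrix averaged over directions."""
    h, w = arr.shape
    maxlen = max(h, w)
    mats = []
    for d in directions:
        mat = np.zeros((levels, maxlen))
        for line in _lines(arr, d):
            i = 0
            while i < len(line):
                j = i
                while j < len(line) and line[j] == line[i]:
                    j += 1
                mat[line[i], j - i - 1] += 1
                i = j
        mats.append(mat)
    return np.mean(mats, axis=0)


def brute_glrlm_features(r: np.ndarray, n_pixels: int) -> dict[str, float]:
    levels, maxlen = r.shape
    n_runs = r.sum()
    out = {k: 0.0 for k in ("sre", "lre", "gln", "rln", "lgre", "hgre",
                            "srlge", "srhge", "lrlge", "lrhge")}
    for i in range(levels):
        for j in range(maxlen):
            v = r[i, j]
            lev, rl = i + 1.0, j + 1.0
            out["sre"] += v / rl ** 2
            out["lre"] += v * rl ** 2
            out["lgre"] += v / lev ** 2
            out["hgre"] += v * lev ** 2
            out["srlge"] += v / (lev * rl) ** 2
            out["srhge"] += v * lev ** 2 / rl ** 2
            out["lrlge"] += v * rl ** 2 / lev ** 2
            out["lrhge"] += v * (lev * rl) ** 2
    out = {f"glrlm_{k}": v / n_runs for k, v in out.items()}
    out["glrlm_gln"] = sum(sum(r[i]) ** 2 for i in range(levels)) / n_runs
    out["glrlm_rln"] = sum(sum(r[:, j]) ** 2 for j in range(maxlen)) / n_runs
    out["glrlm_rp"] = n_runs / n_pixels
    return out


def brute_glds(arr: np.ndarray, levels: int,
               displacements: list[tuple[int, int]]) -> dict[str, float]:
    h, w = arr.shape
    diffs = []
    for dr, dc in displacements:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    diffs.append(abs(int(arr[r, c]) - int(arr[r2, c2])))
    pk = [0.0] * levels
    for d in diffs:
        pk[d] += 1
    pk = [v / len(diffs) for v in pk]
    mean = sum(k * pk[k] for k in range(levels))
    return {
        "glds_mean": mean,
        "glds_variance": sum((k - mean) ** 2 * pk[k] for k in range(levels)),
        "glds_entropy": sum(_h(v) for v in pk),
        "glds_asm": sum(v ** 2 for v in pk),
        "glds_contrast": sum(k ** 2 * pk[k] for k in range(levels)),
    }


def brute_histogram_moments(pixels: np.ndarray) -> dict[str, float]:
    """First-order moments by explicit per-pixel accumulation."""
    x = [float(v) for v in np.asarray(pixels).ravel()]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    std = math.sqrt(var)
    if std < 1e-12:
        skew = kurt = 0.0
    else:
        skew = sum(((v - mean) / std) ** 3 for v in x) / n
        kurt = sum(((v - mean) / std) ** 4 for v in x) / n - 3.0
    return {"hist_mean": mean, "hist_variance": var, "hist_std": std,
            "hist_skewness": skew, "hist_kurtosis": kurt}


def brute_convolve_valid(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct 2-D convolution (kernel flipped), valid region only."""
    kh, kw = kernel.shape
    h, w = x.shape
    out = np.zeros((h - kh + 1, w - kw + 1))
    kf = kernel[::-1, ::-1]
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            out[r, c] = (x[r:r + kh, c:c + kw] * kf).sum()
    return out
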