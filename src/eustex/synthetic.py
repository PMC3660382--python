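"""Seeded two-class speckle textures standing in for clinical ultrasound data.

No imaging cohort accompanies the diagnostic problem this package targets,
so every pipeline stage is exercised on synthetic speckle. An image is the
magnitude of a complex white-noise field smoothed by a Gaussian kernel —
giving Rayleigh-like first-order statistics and a tunable correlation
length, the two signatures of fully developed ultrasound speckle — rescaled
to a target mean echogenicity, with Poisson-placed Gaussian bright blobs
emulating hyperechoic foci (e.g. calcifications in chronic pancreatitis)
and additive sensor noise.

Class realism stops at second-order statistics: there is no anatomy, no
attenuation with depth, no scan-conversion geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .texture_features import FeatureConfig, feature_table

#: Fixed width (pixels) of a hyperechoic focus blob.
FOCUS_SIGMA = 1.5

# per-image seed derivation: Knuth multiplicative hash, kept below 2^31 so
# cohorts reproduce across platforms
_HASH_MULT = 2654435761
_SEED_MOD = 2 ** 31


@dataclass(frozen=True)
class TextureClassParams:
    """Knobs of one texture class.

    correlation_length
        Gaussian smoothing width in pixels; sets the speckle grain size.
    echogenicity
        Target mean intensity (0-255).
    focus_rate
        Expected bright foci per 1,000 px².
    focus_amplitude
        Peak added intensity of a focus.
    noise_sigma
        Standard deviation of additive Gaussian sensor noise.
    """

    correlation_length: float = 3.0
    echogenicity: float = 100.0
    focus_rate: float = 0.5
    focus_amplitude: float = 40.0
    noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        if min(self.correlation_length, self.focus_rate,
               self.focus_amplitude, self.noise_sigma) < 0:
            raise ValueError("texture parameters must be nonnegative")
        if not 0 <= self.echogenicity <= 255:
            raise ValueError("echogenicity must lie in [0, 255]")


#: Default study conditions: the cancer class is darker with fine, tight
#: speckle; the pancreatitis class is brighter, coarser, and rich in
#: hyperechoic foci.
PC_PARAMS = TextureClassParams(correlation_length=2.0, echogenicity=85.0,
                               focus_rate=0.2, focus_amplitude=35.0,
                               noise_sigma=5.0)
CP_PARAMS = TextureClassParams(correlation_length=4.0, echogenicity=115.0,
                               focus_rate=1.5, focus_amplitude=50.0,
                               noise_sigma=5.0)


def correlation_pair(corr_pc: float = 2.0, corr_cp: float = 6.0,
                     ) -> tuple[TextureClassParams, TextureClassParams]:
    """Two classes identical except for the speckle correlation length."""
    base = TextureClassParams(correlation_length=corr_pc, echogenicity=100.0,
                              focus_rate=0.5, focus_amplitude=40.0,
                              noise_sigma=5.0)
    return base, replace(base, correlation_length=corr_cp)


def derive_seed(master_seed: int, index: int) -> int:
    """Documented fixed hash from a master seed to a per-image seed."""
    return (master_seed * _HASH_MULT + 97 + index) % _SEED_MOD


def generate_texture(params: TextureClassParams, size: tuple[int, int],
                     seed: int) -> np.ndarray:
    """One speckled grayscale image, fully determined by ``seed``."""
    h, w = size
    if h < 16 or w < 16:
        raise ValueError("texture size must be at least 16x16")
    rng = np.random.default_rng(seed)
    re = rng.standard_normal((h, w))
    im = rng.standard_normal((h, w))
    if params.correlation_length > 0:
        re = gaussian_filter(re, params.correlation_length, mode="reflect")
        im = gaussian_filter(im, params.correlation_length, mode="reflect")
    mag = np.hypot(re, im)
    mean = mag.mean()
    img = (mag / mean * params.echogenicity if mean > 0
           else np.full((h, w), params.echogenicity))

    n_foci = rng.poisson(params.focus_rate * h * w / 1000.0)
    if n_foci:
        rr, cc = np.meshgrid(np.arange(h, dtype=float),
                             np.arange(w, dtype=float), indexing="ij")
        for _ in range(n_foci):
            r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
            img += params.focus_amplitude * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * FOCUS_SIGMA ** 2))

    if params.noise_sigma > 0:
        img += rng.normal(0.0, params.noise_sigma, size=(h, w))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_cohort(params_pc: TextureClassParams,
                    params_cp: TextureClassParams,
                    n_pc: int, n_cp: int,
                    size: tuple[int, int] = (64, 64),
                    seed: int = 0,
                    ) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Labelled two-class image set with per-image seeds hashed from ``seed``.

    Returns ``(images, labels, case_ids)`` with cancer first (label 1).
    """
    if n_pc < 2 or n_cp < 2:
        raise ValueError("each class needs at least 2 images")
    images, labels, ids = [], [], []
    for i in range(n_pc + n_cp):
        params = params_pc if i < n_pc else params_cp
        label = 1 if i < n_pc else 0
        images.append(generate_texture(params, size, derive_seed(seed, i)))
        labels.append(label)
        ids.append(f"{'pc' if label else 'cp'}{i:04d}")
    return images, np.asarray(labels, dtype=int), ids


def cohort_feature_table(params_pc: TextureClassParams,
                         params_cp: TextureClassParams,
                         n_pc: int, n_cp: int,
                         size: tuple[int, int] = (64, 64),
                         seed: int = 0,
                         config: FeatureConfig = FeatureConfig(),
                         ) -> pd.DataFrame:
    """Generate a cohort and extract its full feature table in one step."""
    images, labels, ids = generate_cohort(params_pc, params_cp, n_pc, n_cp,
                                          size=size, seed=seed)
    return feature_table(images, labels, case_ids=ids, config=config)
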