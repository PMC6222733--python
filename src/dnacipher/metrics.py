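"""Security statistics for the image cipher.

NPCR (number of pixels change rate) and UACI (unified average changing
intensity) quantify how two cipher images C1, C2 differ:

    NPCR = mean(C1 != C2) * 100
    UACI = mean(|C1 - C2| / 255) * 100

For two independent uniformly random 8-bit ciphers the expectations are
(1 - 1/256) * 100 = 99.609...% and ~33.46%. Differential resistance is
measured by encrypting a plain image and a copy with a single perturbed
pixel and comparing the cipher pixel grids (the stage on which the
definitions operate, before DNA encoding), averaged over ten trials.

Adjacent-pixel correlation follows the discrete Pearson formulas with
divisor N over a seeded sample of adjacent pairs (1000 pairs by default):
natural images correlate strongly (r > 0.9); a good cipher decorrelates
(|r| ~ a few 0.01 at this sample size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cipher_core

__all__ = [
    "MetricsReport",
    "adjacent_correlation",
    "differential_trials",
    "key_sensitivity_test",
    "key_space_size",
    "npcr",
    "uaci",
]


def _pair(c1, c2) -> tuple[np.ndarray, np.ndarray]:
    a = cipher_core.as_image(c1)
    b = cipher_core.as_image(c2)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def npcr(c1, c2) -> float:
    """Percentage of positions at which the two images differ."""
    a, b = _pair(c1, c2)
    return float(np.mean(a != b) * 100.0)


def uaci(c1, c2) -> float:
    """Mean absolute pixel difference, normalized by 255, in percent."""
    a, b = _pair(c1, c2)
    return float(np.mean(np.abs(a.astype(np.int16) - b.astype(np.int16)) / 255.0) * 100.0)


_OFFSETS = {"horizontal": (0, 1), "vertical": (1, 0), "diagonal": (1, 1)}


def sample_adjacent_pairs(image, direction: str, n_pairs: int,
                          seed: int | None = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform sample of ``n_pairs`` (pixel, neighbour) values."""
    img = cipher_core.as_image(image)
    try:
        di, dj = _OFFSETS[direction]
    except KeyError:
        raise ValueError(
            f"direction must be one of {sorted(_OFFSETS)}, got {direction!r}"
        ) from None
    h, w = img.shape
    if h - di < 1 or w - dj < 1:
        raise ValueError(f"image too small for {direction} pairs")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, h - di, size=n_pairs)
    j = rng.integers(0, w - dj, size=n_pairs)
    return img[i, j].astype(np.float64), img[i + di, j + dj].astype(np.float64)


def adjacent_correlation(image, direction: str = "horizontal",
                         n_pairs: int = 1000, seed: int | None = 0) -> float:
    """Pearson correlation r_xy of sampled adjacent pixel pairs.

    Uses the discrete formulas with divisor N: E(x) = mean, D(x) = mean
    squared deviation, cov(x, y) = mean cross deviation. Raises for a
    constant sample (zero variance leaves r undefined).
    """
    x, y = sample_adjacent_pairs(image, direction, n_pairs, seed)
    ex, ey = x.mean(), y.mean()
    dx = np.mean((x - ex) ** 2)
    dy = np.mean((y - ey) ** 2)
    if dx == 0.0 or dy == 0.0:
        raise ValueError("correlation undefined for a constant sample")
    cov = np.mean((x - ex) * (y - ey))
    return float(cov / np.sqrt(dx * dy))


def key_space_size(key_len: int = 16, alphabet: int = 256) -> int:
    """Exact number of distinct keys (arbitrary precision)."""
    if key_len < 1 or alphabet < 1:
        raise ValueError("key_len and alphabet must be positive")
    return alphabet**key_len


def key_sensitivity_test(image, key, codebook=None) -> float:
    """Cipher difference (NPCR-style, percent) for a one-byte key change.

    Encrypts the image with ``key`` and with the key whose last byte is
    incremented by 1 (mod 256) and compares the cipher pixel grids.
    ``codebook`` is accepted for interface symmetry but the comparison is
    made at the pixel stage, where the statistic is defined.
    """
    key = bytes(bytearray(key))
    key2 = key[:-1] + bytes([(key[-1] + 1) % 256])
    c1, _ = cipher_core.encrypt_pixels(image, key)
    c2, _ = cipher_core.encrypt_pixels(image, key2)
    return npcr(c1, c2)


@dataclass(frozen=True)
class MetricsReport:
    """Summary of a cipher evaluation run."""

    npcr: float
    uaci: float
    correlations: dict
    key_sensitivity: float | None
    trials: int

    def to_dict(self) -> dict:
        return {
            "npcr": self.npcr,
            "uaci": self.uaci,
            "correlations": self.correlations,
            "key_sensitivity": self.key_sensitivity,
            "trials": self.trials,
        }


def differential_trials(key, shape: tuple[int, int] = (256, 256),
                        n_trials: int = 10, seed: int = 0
                        ) -> tuple[float, float, list[float], list[float]]:
    """Ten-trial one-pixel-difference experiment on uniform-random images.

    Each trial draws a fresh image and a fresh perturbation position from
    the trial's own seeded generator, perturbs that pixel by +1 mod 256,
    encrypts both images with ``key`` and records NPCR and UACI between the
    cipher pixel grids. Returns (mean NPCR, mean UACI, per-trial lists).
    """
    npcrs: list[float] = []
    uacis: list[float] = []
    for t in range(n_trials):
        rng = np.random.default_rng([seed, t])
        img = rng.integers(0, 256, size=shape, dtype=np.uint8)
        i = int(rng.integers(0, shape[0]))
        j = int(rng.integers(0, shape[1]))
        img2 = img.copy()
        img2[i, j] = (int(img2[i, j]) + 1) % 256
        c1, _ = cipher_core.encrypt_pixels(img, key)
        c2, _ = cipher_core.encrypt_pixels(img2, key)
        npcrs.append(npcr(c1, c2))
        uacis.append(uaci(c1, c2))
    return float(np.mean(npcrs)), float(np.mean(uacis)), npcrs, uacis
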