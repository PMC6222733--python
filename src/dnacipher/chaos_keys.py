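"""Key schedule and logistic-map keystream for the image cipher.

The secret key is 16 bytes. Encryption first folds the plaintext into the
key: every key element is XORed with every pixel value, i.e.

    relating_key[j] = key[j] XOR (XOR of all pixels)

so the *relating key* depends on the whole image and any single-pixel change
alters all sixteen bytes — which in turn moves all four chaotic parameters
and gives the cipher its plaintext sensitivity (NPCR ~ 99.6%).

The relating key is divided evenly into four 4-byte parts, read big-endian
as 32-bit integers v, which fix two logistic maps x_{i+1} = mu x_i (1 - x_i):

    mu   = 3.9 + 0.1 * v / (2^32 - 1)        (parts 1 and 2; mu in [3.9, 4])
    x(0) = (v + 1) / (2^32 + 2)              (parts 3 and 4; x(0) in (0, 1))

Each map is burned in for 100 iterations to shed the transient, then iterated
once per pixel it serves: the first map covers the first half of the pixels
in row-major order, the second the rest. The same orbit values drive both
stages of the cipher — their ascending sort order defines the permutation,
and floor(x * 10^14) mod 256 quantizes them into keystream bytes.

All derivations are fixed bit-exactly (big-endian reads, IEEE doubles) so
that ciphertexts are reproducible across implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChaoticParams",
    "DegenerateOrbitError",
    "derive_relating_key",
    "keystream_bytes",
    "logistic_orbit",
    "orbits_for_pixels",
    "params_from_relating_key",
    "parse_key",
    "permutation_from_orbits",
]

KEY_LEN = 16
BURN_IN = 100

_U32 = 2**32


@dataclass(frozen=True)
class ChaoticParams:
    """Parameters and initial values of the two logistic maps."""

    mu1: float
    mu2: float
    x1_0: float
    x2_0: float


def parse_key(text: str) -> bytes:
    """Interpret a key string as 16 bytes.

    A 32-hex-digit string is decoded as hex; anything else is taken as ASCII
    and right-padded with zero bytes (or truncated) to 16 bytes, so that
    human-readable keys such as ``"123456789012345"`` (15 characters) are
    accepted.
    """
    if len(text) == 32:
        try:
            return bytes.fromhex(text)
        except ValueError:
            pass
    raw = text.encode("ascii")
    return raw[:KEY_LEN].ljust(KEY_LEN, b"\x00")


def _check_key(key) -> np.ndarray:
    arr = np.asarray(bytearray(key) if isinstance(key, (bytes, bytearray)) else key)
    if arr.shape != (KEY_LEN,):
        raise ValueError(f"key must be {KEY_LEN} bytes, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValueError("key bytes must be in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def plaintext_fold(image: np.ndarray) -> int:
    """XOR of every pixel value — the one-byte digest folded into the key."""
    flat = np.asarray(image, dtype=np.uint8).ravel()
    if flat.size == 0:
        raise ValueError("cannot fold an empty image")
    return int(np.bitwise_xor.reduce(flat))


def derive_relating_key(key, image: np.ndarray) -> bytes:
    """Fold the plain image into the key: each byte XORed with every pixel."""
    k = _check_key(key)
    fold = plaintext_fold(image)
    return bytes(int(b) ^ fold for b in k)


def params_from_relating_key(relating_key) -> ChaoticParams:
    """Map the four big-endian 32-bit parts onto (mu1, mu2, x1_0, x2_0).

    The affine maps hit the closed interval [3.9, 4] exactly at the byte
    extremes and keep the initial values strictly inside (0, 1).
    """
    rk = _check_key(relating_key)
    v = [int.from_bytes(bytes(rk[i : i + 4].tolist()), "big") for i in (0, 4, 8, 12)]
    mu1 = 3.9 + 0.1 * v[0] / (_U32 - 1)
    mu2 = 3.9 + 0.1 * v[1] / (_U32 - 1)
    x1 = (v[2] + 1) / (_U32 + 2)
    x2 = (v[3] + 1) / (_U32 + 2)
    return ChaoticParams(mu1=mu1, mu2=mu2, x1_0=x1, x2_0=x2)


class DegenerateOrbitError(ValueError):
    """The orbit hit 0 or 1 exactly and would collapse to the fixed point.

    The key schedule recovers by perturbing ``x0`` by one representable step
    (see :func:`orbits_for_pixels`); ``x0`` carries the offending start.
    """

    def __init__(self, x0: float, step: int):
        super().__init__(
            f"logistic orbit from x0={x0!r} became degenerate at step {step}; "
            "perturb x0 by the smallest representable step and retry"
        )
        self.x0 = x0
        self.step = step


def logistic_orbit(mu: float, x0: float, burn_in: int = BURN_IN, length: int = 0) -> np.ndarray:
    """Iterate x <- mu x (1 - x), discard ``burn_in`` steps, return ``length``.

    Raises :class:`DegenerateOrbitError` if an iterate leaves the open
    interval (0, 1) — e.g. mu = 4, x0 = 0.5 maps to exactly 1 and then
    collapses onto 0.
    """
    if not 3.9 <= mu <= 4.0:
        raise ValueError(f"mu={mu} outside [3.9, 4]")
    if not 0.0 < x0 < 1.0:
        raise ValueError(f"x0={x0} outside (0, 1)")
    x = float(x0)
    out = np.empty(length, dtype=np.float64)
    for i in range(burn_in + length):
        x = mu * x * (1.0 - x)
        if x <= 0.0 or x >= 1.0:
            raise DegenerateOrbitError(x0, i + 1)
        if i >= burn_in:
            out[i - burn_in] = x
    return out


def _safe_orbit(mu: float, x0: float, burn_in: int, length: int,
                max_retries: int = 64) -> np.ndarray:
    """Orbit with the documented recovery: nudge x0 one ulp on collapse."""
    x = x0
    for _ in range(max_retries):
        try:
            return logistic_orbit(mu, x, burn_in, length)
        except DegenerateOrbitError:
            x = math.nextafter(x, 1.0) if x < 0.5 else math.nextafter(x, 0.0)
    raise DegenerateOrbitError(x0, -1)


def orbits_for_pixels(params: ChaoticParams, n_pixels: int,
                      burn_in: int = BURN_IN) -> tuple[np.ndarray, np.ndarray]:
    """The two orbits serving an n-pixel image: first map takes ceil(n/2)."""
    if n_pixels < 1:
        raise ValueError("image must have at least one pixel")
    n1 = (n_pixels + 1) // 2
    o1 = _safe_orbit(params.mu1, params.x1_0, burn_in, n1)
    o2 = _safe_orbit(params.mu2, params.x2_0, burn_in, n_pixels - n1)
    return o1, o2


def keystream_bytes(orbit1: np.ndarray, orbit2: np.ndarray) -> np.ndarray:
    """Quantize orbit values into bytes: floor(x * 10^14) mod 256.

    The deep-mantissa digits of the double-precision iterates are used so
    that nearby orbit values still produce decorrelated bytes.
    """
    o = np.concatenate([np.asarray(orbit1, float), np.asarray(orbit2, float)])
    return (np.floor(o * 1e14).astype(np.int64) % 256).astype(np.uint8)


def permutation_from_orbits(orbit1: np.ndarray, orbit2: np.ndarray,
                            n: int) -> np.ndarray:
    """Stable ascending argsort of the concatenated orbits.

    ``perm[k]`` is the source index of the k-th smallest orbit value; ties
    keep original order, so the result is always a bijection on 0..n-1.
    """
    o = np.concatenate([np.asarray(orbit1, float), np.asarray(orbit2, float)])
    if o.size != n:
        raise ValueError(f"orbit length {o.size} does not match n={n}")
    return np.argsort(o, kind="stable")
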