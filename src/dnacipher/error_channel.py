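"""Substitution-error channel and minimum-distance correction.

A hybridization readout can substitute single bases in the DNA cipher.
Because the codebook is certified with minimum pairwise Hamming distance
d_min = 3, every word within distance 1 of a codeword has that codeword as
its unique nearest neighbour, so nearest-codeword decoding restores any
single-base substitution exactly. A received word with no codeword inside
the correction radius floor((d_min - 1) / 2) — or, defensively, with a tie —
is forced to the sentinel pixel 255; the :class:`ErrorReport`, not the pixel
grid, is the authoritative record of such fallbacks (255 is also a
legitimate pixel value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cipher_core import DnaCipher
from .dna_codes import SENTINEL_PIXEL, Codebook, _check_word

__all__ = [
    "ErrorReport",
    "correct_cipher",
    "correct_word",
    "decode_cipher",
    "inject_errors",
]

_ASCII_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorReport:
    """Tally of a decode/correction pass over a cipher."""

    injected: int = 0
    exact: int = 0
    corrected: int = 0
    fallback_count: int = 0
    residual_pixel_diffs: int | None = None

    def to_dict(self) -> dict:
        return {
            "injected": self.injected,
            "exact": self.exact,
            "corrected": self.corrected,
            "fallback_count": self.fallback_count,
            "residual_pixel_diffs": self.residual_pixel_diffs,
        }


def inject_errors(cipher: DnaCipher, n_errors: int, seed: int) -> DnaCipher:
    """Corrupt ``n_errors`` distinct codewords at one random base each.

    Word positions are sampled uniformly without replacement; within each
    chosen word one base position is uniform and the replacement base is
    uniform over the three alternatives, so every corrupted word ends at
    Hamming distance exactly 1 from its original. Deterministic per seed.
    """
    if n_errors < 0:
        raise ValueError("n_errors must be non-negative")
    if n_errors > cipher.n_words:
        raise ValueError(
            f"cannot corrupt {n_errors} words; cipher has {cipher.n_words}"
        )
    out = cipher.copy()
    if n_errors == 0:
        return out
    rng = np.random.default_rng(seed)
    word_idx = rng.choice(cipher.n_words, size=n_errors, replace=False)
    base_idx = rng.integers(0, cipher.word_length, size=n_errors)
    current = out.words[word_idx, base_idx]
    # map each current base to one of its three alternatives, uniformly
    alt = rng.integers(0, 3, size=n_errors)
    cur_rank = np.searchsorted(np.sort(_ASCII_BASES), current)
    new_rank = alt + (alt >= cur_rank)
    out.words[word_idx, base_idx] = np.sort(_ASCII_BASES)[new_rank]
    return out


def _word_to_ascii(word: str) -> np.ndarray:
    return np.frombuffer(word.encode("ascii"), dtype=np.uint8)


def correct_word(word: str, codebook: Codebook) -> tuple[int, str]:
    """Minimum-distance decode one word: (pixel, status).

    Status is ``"exact"`` for a codeword, ``"corrected"`` when exactly one
    codeword lies within the correction radius, else ``"fallback"`` with the
    sentinel pixel.
    """
    w = _check_word(word)
    if len(w) != codebook.word_length:
        raise ValueError(
            f"word length {len(w)} does not match codebook "
            f"({codebook.word_length})"
        )
    pixel = codebook.pixel(w)
    if pixel is not None:
        return pixel, "exact"
    dists = (codebook.ascii_matrix() != _word_to_ascii(w)).sum(axis=1)
    within = np.nonzero(dists <= codebook.correction_radius)[0]
    if within.size == 1:
        return int(within[0]), "corrected"
    return SENTINEL_PIXEL, "fallback"


def decode_cipher(cipher: DnaCipher, codebook: Codebook,
                  correct: bool = True) -> tuple[np.ndarray, ErrorReport]:
    """Decode every word of a cipher to pixel values.

    Strict mode (``correct=False``) maps non-codewords straight to the
    sentinel; with correction, radius-limited nearest-codeword decoding is
    attempted first. Exact lookups are hash-based; only the (typically few)
    corrupted words pay the vectorized distance scan.
    """
    if cipher.word_length != codebook.word_length:
        raise ValueError("cipher and codebook word lengths differ")
    book = codebook.ascii_matrix()
    lookup = {book[p].tobytes(): p for p in range(256)}
    pixels = np.empty(cipher.n_words, dtype=np.uint8)
    miss_idx = []
    raw = cipher.words
    for i in range(cipher.n_words):
        p = lookup.get(raw[i].tobytes())
        if p is None:
            miss_idx.append(i)
            pixels[i] = SENTINEL_PIXEL
        else:
            pixels[i] = p
    corrected = 0
    fallback = len(miss_idx)
    if correct and miss_idx:
        fallback = 0
        radius = codebook.correction_radius
        miss = np.asarray(miss_idx)
        # distances of every missed word to all 256 codewords
        d = (raw[miss][:, None, :] != book[None, :, :]).sum(axis=2)
        hits = d <= radius
        n_hits = hits.sum(axis=1)
        for row, i in enumerate(miss):
            if n_hits[row] == 1:
                pixels[i] = int(np.nonzero(hits[row])[0][0])
                corrected += 1
            else:
                pixels[i] = SENTINEL_PIXEL
                fallback += 1
    report = ErrorReport(
        injected=len(miss_idx),
        exact=cipher.n_words - len(miss_idx),
        corrected=corrected,
        fallback_count=fallback,
    )
    return pixels, report


def correct_cipher(cipher: DnaCipher, codebook: Codebook,
                   original: DnaCipher | None = None
                   ) -> tuple[DnaCipher, ErrorReport]:
    """Rewrite every correctable word to its codeword; idempotent.

    When the pre-corruption ``original`` is supplied, the report's
    ``residual_pixel_diffs`` counts decoded-pixel differences that remain
    after correction (0 when every injected error was repaired).
    """
    pixels, rep = decode_cipher(cipher, codebook, correct=True)
    out = cipher.copy()
    out.words = codebook.ascii_matrix()[pixels]
    residual = None
    if original is not None:
        orig_pixels, _ = decode_cipher(original, codebook, correct=False)
        residual = int(np.count_nonzero(orig_pixels != pixels))
    report = ErrorReport(
        injected=rep.injected,
        exact=rep.exact,
        corrected=rep.corrected,
        fallback_count=rep.fallback_count,
        residual_pixel_diffs=residual,
    )
    return out, report
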