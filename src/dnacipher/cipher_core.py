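"""Permutation-diffusion encryption with DNA-codebook output.

Encryption of an H x W 8-bit grayscale image proceeds as:

1. fold the plaintext into the 16-byte key (relating key);
2. derive the two logistic maps' parameters from the relating key and
   generate one orbit value per pixel (100-iterate burn-in);
3. *permutation* — relocate pixels by the ascending sort order of the
   orbit values (gather convention: output flat pixel k = input flat pixel
   perm[k], row-major);
4. *diffusion* — XOR each permuted pixel with its quantized keystream byte;
5. encode every cipher pixel as the DNA codeword of its value.

The result is a :class:`DnaCipher`: a row-major grid of octamers, the object
on which a hybridization channel acts and on which substitution errors can
be corrected codeword-by-codeword (see :mod:`dnacipher.error_channel`).

Decryption inverts the steps. It needs the relating key, which depends on
the plaintext; the cipher container therefore carries the one-byte
plaintext XOR digest, and the decryptor reconstructs
``relating_key = key XOR digest`` — without the secret key the keystream
and permutation cannot be regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chaos_keys
from .dna_codes import Codebook

__all__ = [
    "DnaCipher",
    "as_image",
    "decrypt",
    "diffuse",
    "encrypt",
    "encrypt_pixels",
    "inverse_permute",
    "permute",
    "read_cipher",
    "write_cipher",
]

_MAGIC = "#dnacipher 1"


def as_image(pixels) -> np.ndarray:
    """Validate/convert to a 2-D uint8 image matrix."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("an image must be a non-empty 2-D matrix")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValueError("pixel values must be in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


@dataclass(eq=False)
class DnaCipher:
    """A DNA-encoded cipher image.

    ``words`` holds the H*W codewords row-major as an (N, L) uint8 matrix of
    ASCII base codes (compact and cheap to mutate base-wise). ``fold`` is
    the one-byte plaintext XOR digest needed to rebuild the relating key.
    """

    words: np.ndarray
    height: int
    width: int
    codebook_id: str
    fold: int = 0

    def __post_init__(self) -> None:
        self.words = np.ascontiguousarray(self.words, dtype=np.uint8)
        if self.words.ndim != 2:
            raise ValueError("words must be an (N, word_length) matrix")
        if self.words.shape[0] != self.height * self.width:
            raise ValueError(
                f"{self.words.shape[0]} words for a "
                f"{self.height}x{self.width} image"
            )
        if not 0 <= self.fold <= 255:
            raise ValueError("fold digest must be one byte")

    @property
    def n_words(self) -> int:
        return self.words.shape[0]

    @property
    def word_length(self) -> int:
        return self.words.shape[1]

    def word(self, i: int) -> str:
        return self.words[i].tobytes().decode("ascii")

    def to_strings(self) -> list[str]:
        return [self.word(i) for i in range(self.n_words)]

    def copy(self) -> "DnaCipher":
        return DnaCipher(
            words=self.words.copy(),
            height=self.height,
            width=self.width,
            codebook_id=self.codebook_id,
            fold=self.fold,
        )

    def same_words(self, other: "DnaCipher") -> bool:
        return (
            self.words.shape == other.words.shape
            and bool(np.array_equal(self.words, other.words))
        )


def permute(image: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Relocate pixels: output flat pixel k = input flat pixel perm[k].

    Only positions change; the pixel-value histogram is preserved.
    """
    img = as_image(image)
    perm = np.asarray(perm)
    n = img.size
    if perm.shape != (n,):
        raise ValueError(f"permutation length {perm.size} != pixel count {n}")
    if not np.array_equal(np.sort(perm), np.arange(n)):
        raise ValueError("perm is not a bijection on 0..n-1")
    return img.ravel()[perm].reshape(img.shape)


def inverse_permute(image: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Undo :func:`permute` with the same index vector."""
    img = as_image(image)
    perm = np.asarray(perm)
    n = img.size
    if perm.shape != (n,):
        raise ValueError(f"permutation length {perm.size} != pixel count {n}")
    out = np.empty(n, dtype=np.uint8)
    out[perm] = img.ravel()
    return out.reshape(img.shape)


def diffuse(image: np.ndarray, keystream: np.ndarray) -> np.ndarray:
    """XOR every pixel with its keystream byte; an involution."""
    img = as_image(image)
    ks = np.asarray(keystream, dtype=np.uint8)
    if ks.size != img.size:
        raise ValueError(
            f"keystream length {ks.size} != pixel count {img.size}"
        )
    return (img.ravel() ^ ks).reshape(img.shape)


def _stream_for(relating_key: bytes, n: int) -> tuple[np.ndarray, np.ndarray]:
    params = chaos_keys.params_from_relating_key(relating_key)
    o1, o2 = chaos_keys.orbits_for_pixels(params, n)
    perm = chaos_keys.permutation_from_orbits(o1, o2, n)
    ks = chaos_keys.keystream_bytes(o1, o2)
    return perm, ks


def encrypt_pixels(image: np.ndarray, key) -> tuple[np.ndarray, bytes]:
    """Permutation + diffusion only; returns (cipher pixels, relating key).

    This is the stage on which the pixel-level security statistics (NPCR,
    UACI, key sensitivity) are defined.
    """
    img = as_image(image)
    relating_key = chaos_keys.derive_relating_key(key, img)
    perm, ks = _stream_for(relating_key, img.size)
    return diffuse(permute(img, perm), ks), relating_key


def encrypt(image: np.ndarray, key, codebook: Codebook) -> DnaCipher:
    """Full pipeline: permute, diffuse, then DNA-encode every cipher pixel."""
    img = as_image(image)
    cipher_pixels, _ = encrypt_pixels(img, key)
    words = codebook.ascii_matrix()[cipher_pixels.ravel()]
    return DnaCipher(
        words=words,
        height=img.shape[0],
        width=img.shape[1],
        codebook_id=codebook.name,
        fold=chaos_keys.plaintext_fold(img),
    )


def decrypt(cipher: DnaCipher, key, codebook: Codebook,
            correct: bool = False) -> np.ndarray:
    """Invert :func:`encrypt`.

    ``correct=True`` applies minimum-distance correction to each received
    word before decoding; otherwise a word that is not an exact codeword
    decodes to the sentinel pixel 255 rather than raising.
    """
    from .error_channel import decode_cipher  # local import; avoids a cycle

    k = np.asarray(bytearray(key) if isinstance(key, (bytes, bytearray)) else key,
                   dtype=np.uint8)
    relating_key = bytes(int(b) ^ cipher.fold for b in k)
    pixels, _ = decode_cipher(cipher, codebook, correct=correct)
    perm, ks = _stream_for(relating_key, cipher.n_words)
    permuted = diffuse(pixels.reshape(cipher.height, cipher.width), ks)
    return inverse_permute(permuted, perm)


def write_cipher(cipher: DnaCipher, path) -> None:
    """Plain-text container: header lines, then one row of words per line."""
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(f"#height {cipher.height}\n")
        fh.write(f"#width {cipher.width}\n")
        fh.write(f"#word_length {cipher.word_length}\n")
        fh.write(f"#codebook {cipher.codebook_id}\n")
        fh.write(f"#fold {cipher.fold:02x}\n")
        words = cipher.words.reshape(cipher.height, cipher.width * cipher.word_length)
        for row in words:
            fh.write(row.tobytes().decode("ascii") + "\n")


def read_cipher(path) -> DnaCipher:
    """Read a container written by :func:`write_cipher`."""
    header: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _MAGIC:
            raise ValueError(f"{path} is not a DNA cipher container")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line[1:].partition(" ")
                header[k] = v
            elif line:
                rows.append(line)
    height = int(header["height"])
    width = int(header["width"])
    wl = int(header["word_length"])
    if len(rows) != height or any(len(r) != width * wl for r in rows):
        raise ValueError(f"{path}: malformed word grid")
    words = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return DnaCipher(
        words=words.reshape(height * width, wl),
        height=height,
        width=width,
        codebook_id=header.get("codebook", "unknown"),
        fold=int(header.get("fold", "00"), 16),
    )
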