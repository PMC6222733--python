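"""DNA codeword sets under combined Hamming-distance and GC-content constraints.

A codeword set ``C`` over the alphabet ``{A, C, G, T}`` is certified for a
distance parameter ``d`` and a GC-content target when, for every member ``u``:

* **SS** (sequence-sequence): ``min_{v != u} H(u, v) >= d`` — no two codewords
  are mutually similar, which suppresses false-positive hybridization between
  two coding strands;
* **SC** (sequence-complementarity): ``min_{v != u} H(u, rc(v)) >= d`` where
  ``rc`` is the reverse complement — no codeword resembles the Watson-Crick
  partner of another, which suppresses spurious cross-hybridization;
* **GC**: the fraction of G/C bases equals the target (50% here), keeping
  melting temperatures of all codewords comparable.

A set with minimum pairwise distance ``d`` supports minimum-distance decoding
that corrects up to ``floor((d - 1) / 2)`` substitutions per codeword; the
default configuration (octamers, d = 3, GC = 50%) corrects one substituted
base per pixel.

The designer in :func:`design_code_set` is a seeded stochastic greedy search
with restarts over the GC-balanced candidate space, not an exact maximum-set
solver; it is sufficient to reach 256 octamers at d = 3 (sets of size > 300
are found routinely, and sets of size 336 are known to exist).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BASES",
    "CodeSet",
    "Codebook",
    "DesignError",
    "ValidationReport",
    "WordCheck",
    "build_codebook",
    "design_code_set",
    "gc_content",
    "hamming_distance",
    "read_codebook_tsv",
    "reverse_complement",
    "sc_distance",
    "ss_distance",
    "validate_code_set",
    "write_codebook_tsv",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SENTINEL_PIXEL = 255


def _check_word(word: str) -> str:
    if not isinstance(word, str) or len(word) == 0:
        raise ValueError("a DNA word must be a non-empty string")
    w = word.upper()
    if any(b not in _BASE_INDEX for b in w):
        raise ValueError(f"invalid base in DNA word {word!r}; alphabet is ACGT")
    return w


def hamming_distance(u: str, v: str) -> int:
    """Number of positions at which two equal-length DNA words differ."""
    u, v = _check_word(u), _check_word(v)
    if len(u) != len(v):
        raise ValueError(
            f"words of length {len(u)} and {len(v)} are incomparable"
        )
    return sum(a != b for a, b in zip(u, v))


def reverse_complement(word: str) -> str:
    """Watson-Crick partner: complement each base (A<->T, C<->G), read 3'->5'.

    An involution: ``reverse_complement(reverse_complement(w)) == w``.
    """
    return _check_word(word).translate(_COMPLEMENT)[::-1]


def gc_content(word: str) -> float:
    """Percentage of G or C bases in the word."""
    w = _check_word(word)
    return 100.0 * sum(b in "GC" for b in w) / len(w)


def _words_matrix(words: Sequence[str]) -> np.ndarray:
    """Words as an (n, L) uint8 matrix of base indices."""
    return np.array([[_BASE_INDEX[b] for b in w] for w in words], dtype=np.uint8)


def _rc_matrix(mat: np.ndarray) -> np.ndarray:
    # complement index: A<->T is 0<->3, C<->G is 1<->2, i.e. 3 - i
    return (3 - mat)[:, ::-1]


@dataclass(frozen=True)
class CodeSet:
    """An ordered collection of distinct equal-length DNA words.

    ``d_min`` and ``gc_target`` record the constraints the set was designed
    (or validated) against; certification is re-checkable at any time with
    :func:`validate_code_set`.
    """

    words: tuple[str, ...]
    d_min: int = 3
    gc_target: float = 50.0

    def __post_init__(self) -> None:
        words = tuple(_check_word(w) for w in self.words)
        object.__setattr__(self, "words", words)
        if not words:
            raise ValueError("empty code set")
        length = len(words[0])
        if any(len(w) != length for w in words):
            raise ValueError("all words in a code set must have equal length")
        if len(set(words)) != len(words):
            raise ValueError("code set contains duplicate words")

    @property
    def word_length(self) -> int:
        return len(self.words[0])

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)


def _as_words(code_set: CodeSet | Sequence[str]) -> tuple[str, ...]:
    if isinstance(code_set, CodeSet):
        return code_set.words
    words = tuple(_check_word(w) for w in code_set)
    if len({len(w) for w in words}) > 1:
        raise ValueError("mixed-length words")
    return words


def ss_distance(i: int, code_set: CodeSet | Sequence[str]) -> int:
    """Minimum Hamming distance from word ``i`` to every other set member."""
    words = _as_words(code_set)
    if len(words) < 2:
        raise ValueError("SS distance needs at least two words")
    u = words[i]
    return min(hamming_distance(u, v) for j, v in enumerate(words) if j != i)


def sc_distance(i: int, code_set: CodeSet | Sequence[str]) -> int:
    """Minimum Hamming distance from word ``i`` to the reverse complement of
    every *other* member (the self term is excluded)."""
    words = _as_words(code_set)
    if len(words) < 2:
        raise ValueError("SC distance needs at least two words")
    u = words[i]
    return min(
        hamming_distance(u, reverse_complement(v))
        for j, v in enumerate(words)
        if j != i
    )


@dataclass(frozen=True)
class WordCheck:
    word: str
    ss: int
    sc: int
    gc: float
    ok: bool


@dataclass(frozen=True)
class ValidationReport:
    entries: tuple[WordCheck, ...]
    d: int
    gc_target: float
    passed: bool

    def failures(self) -> tuple[WordCheck, ...]:
        return tuple(e for e in self.entries if not e.ok)


def validate_code_set(
    code_set: CodeSet | Sequence[str], d: int, gc_target: float = 50.0
) -> ValidationReport:
    """Check SS >= d, SC >= d and GC == gc_target for every word.

    Vectorized over all pairs; the per-word report lists the attained SS, SC
    and GC values so a failing set can be diagnosed.
    """
    words = _as_words(code_set)
    if len(words) < 2:
        raise ValueError("cannot validate a singleton code set")
    mat = _words_matrix(words)
    rc = _rc_matrix(mat)
    # pairwise distance matrices; diagonal masked out per the SS/SC definitions
    dss = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    dsc = (mat[:, None, :] != rc[None, :, :]).sum(axis=2)
    np.fill_diagonal(dss, mat.shape[1] + 1)
    np.fill_diagonal(dsc, mat.shape[1] + 1)
    ss = dss.min(axis=1)
    sc = dsc.min(axis=1)
    entries = []
    for i, w in enumerate(words):
        gc = gc_content(w)
        ok = ss[i] >= d and sc[i] >= d and gc == gc_target
        entries.append(WordCheck(w, int(ss[i]), int(sc[i]), gc, bool(ok)))
    return ValidationReport(
        entries=tuple(entries),
        d=d,
        gc_target=gc_target,
        passed=all(e.ok for e in entries),
    )


class DesignError(RuntimeError):
    """Raised when the stochastic search cannot reach the requested set size.

    ``best_size`` reports the largest certified set found within the budget.
    """

    def __init__(self, message: str, best_size: int):
        super().__init__(message)
        self.best_size = best_size


def _gc_balanced_candidates(n: int, gc_target: float) -> np.ndarray:
    gc_count = gc_target / 100.0 * n
    if abs(gc_count - round(gc_count)) > 1e-9:
        raise ValueError(
            f"gc_target {gc_target}% is unreachable exactly for length {n}"
        )
    gc_count = int(round(gc_count))
    if n > 12:
        raise ValueError("candidate enumeration supported for lengths <= 12")
    cands = [
        word
        for word in itertools.product(range(4), repeat=n)
        if sum(1 for b in word if b in (1, 2)) == gc_count  # C=1, G=2
    ]
    return np.array(cands, dtype=np.uint8)


def _greedy_pass(
    cands: np.ndarray,
    order: np.ndarray,
    d: int,
    size_target: int,
    preaccepted: np.ndarray,
) -> list[int]:
    """One greedy sweep: accept a candidate iff it keeps SS/SC >= d."""
    acc_idx: list[int] = []
    n_pre = preaccepted.shape[0]
    cap = size_target + 16
    acc = np.empty((cap + n_pre, cands.shape[1]), dtype=np.uint8)
    acc[:n_pre] = preaccepted
    acc_rc = np.empty_like(acc)
    acc_rc[:n_pre] = _rc_matrix(preaccepted)
    count = n_pre
    for idx in order:
        u = cands[idx]
        if count:
            if ((acc[:count] != u).sum(axis=1) < d).any():
                continue
            if ((acc_rc[:count] != u).sum(axis=1) < d).any():
                continue
        acc[count] = u
        acc_rc[count] = _rc_matrix(u[None, :])[0]
        count += 1
        acc_idx.append(int(idx))
        if count - n_pre >= size_target:
            break
    return acc_idx


def _indices_to_words(mat: np.ndarray) -> list[str]:
    return ["".join(BASES[b] for b in row) for row in mat]


def design_code_set(
    n: int,
    d: int,
    gc_target: float = 50.0,
    size_target: int = 256,
    seed: int = 0,
    max_restarts: int = 8,
    include: Sequence[str] = (),
) -> CodeSet:
    """Design a certified code set by seeded stochastic greedy search.

    Candidates are the GC-balanced words of length ``n``, visited in a seeded
    random order; a word is accepted iff it keeps SS and SC at least ``d``
    against everything accepted so far. On a stall the search restarts with a
    fresh shuffle (up to ``max_restarts`` sweeps), keeping the best result.

    ``include`` pins words that must appear (in order) at the front of the
    returned set — used to extend a published partial codebook. Deterministic
    for a fixed ``(seed, include)``.

    Raises :class:`DesignError` (with ``best_size``) if ``size_target`` is not
    reached, and :class:`ValueError` for infeasible parameters (``d > n``).
    """
    if n <= 0 or d <= 0 or size_target <= 0:
        raise ValueError("n, d and size_target must be positive")
    if d > n:
        raise ValueError(f"minimum distance {d} is infeasible for length {n}")
    cands = _gc_balanced_candidates(n, gc_target)
    include = tuple(_check_word(w) for w in include)
    if include:
        rep = validate_code_set(include, d, gc_target) if len(include) > 1 else None
        if rep is not None and not rep.passed:
            raise ValueError("pinned words do not satisfy the constraints")
        if any(len(w) != n for w in include):
            raise ValueError("pinned words have the wrong length")
    pre = (
        _words_matrix(include)
        if include
        else np.empty((0, n), dtype=np.uint8)
    )
    want = size_target - len(include)
    if want <= 0:
        return CodeSet(include[:size_target], d_min=d, gc_target=gc_target)

    best: list[int] = []
    for attempt in range(max_restarts):
        rng = np.random.default_rng([seed, attempt])
        order = rng.permutation(len(cands))
        acc = _greedy_pass(cands, order, d, want, pre)
        if len(acc) > len(best):
            best = acc
        if len(best) >= want:
            break
    if len(best) < want:
        raise DesignError(
            f"reached only {len(include) + len(best)} of {size_target} words "
            f"for (n={n}, d={d}, GC={gc_target}%)",
            best_size=len(include) + len(best),
        )
    words = list(include) + _indices_to_words(cands[best])
    return CodeSet(tuple(words), d_min=d, gc_target=gc_target)


@dataclass(frozen=True)
class Codebook:
    """Bijection between the 256 pixel values and DNA codewords.

    ``words[p]`` is the codeword of pixel value ``p``. ``d_min`` is the
    certified minimum pairwise distance, from which the correction radius
    ``floor((d_min - 1) / 2)`` follows. Pixel :data:`SENTINEL_PIXEL` doubles
    as the fallback value for uncorrectable words, exactly as the sentinel
    convention of the cryptosystem prescribes.
    """

    words: tuple[str, ...]
    d_min: int = 3
    gc_target: float = 50.0
    name: str = "codebook"
    _pixel_of: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.words) != 256:
            raise ValueError(f"a codebook needs 256 words, got {len(self.words)}")
        words = tuple(_check_word(w) for w in self.words)
        object.__setattr__(self, "words", words)
        if len(set(words)) != 256:
            raise ValueError("codebook mapping is not injective")
        if len({len(w) for w in words}) != 1:
            raise ValueError("codebook words must share one length")
        object.__setattr__(
            self, "_pixel_of", {w: p for p, w in enumerate(words)}
        )

    @property
    def word_length(self) -> int:
        return len(self.words[0])

    @property
    def correction_radius(self) -> int:
        return (self.d_min - 1) // 2

    def word(self, pixel: int) -> str:
        if not 0 <= int(pixel) <= 255:
            raise ValueError(f"pixel {pixel} out of range [0, 255]")
        return self.words[int(pixel)]

    def pixel(self, word: str) -> int | None:
        """Exact-match lookup; ``None`` when the word is not a codeword."""
        return self._pixel_of.get(_check_word(word))

    def ascii_matrix(self) -> np.ndarray:
        """(256, L) uint8 array of ASCII base codes, for vectorized encoding."""
        return np.frombuffer(
            "".join(self.words).encode("ascii"), dtype=np.uint8
        ).reshape(256, self.word_length)

    def validate(self) -> ValidationReport:
        return validate_code_set(self.words, self.d_min, self.gc_target)


def build_codebook(
    code_set: CodeSet, selection_seed: int | None = None, name: str | None = None
) -> Codebook:
    """Select 256 words from a certified set and assign them to pixels 0..255.

    With ``selection_seed=None`` the first 256 words are taken in set order
    (this is how a published partial table keeps its printed pixel
    assignments); with a seed, 256 words are drawn without replacement at
    random.
    """
    if len(code_set) < 256:
        raise ValueError(
            f"code set has {len(code_set)} words; 256 are needed"
        )
    if selection_seed is None:
        chosen = code_set.words[:256]
    else:
        rng = np.random.default_rng(selection_seed)
        idx = rng.choice(len(code_set), size=256, replace=False)
        chosen = tuple(code_set.words[i] for i in idx)
    return Codebook(
        words=chosen,
        d_min=code_set.d_min,
        gc_target=code_set.gc_target,
        name=name or f"codebook-{'ordered' if selection_seed is None else selection_seed}",
    )


def write_codebook_tsv(codebook: Codebook, path) -> None:
    """Two-column plain text: pixel value TAB codeword, one row per pixel."""
    with open(path, "w") as fh:
        for pixel, word in enumerate(codebook.words):
            fh.write(f"{pixel}\t{word}\n")


def read_codebook_tsv(path, d_min: int = 3, gc_target: float = 50.0,
                      name: str | None = None) -> Codebook:
    """Read and re-validate a pixel/word table written by
    :func:`write_codebook_tsv` (alphabet, bijectivity, 256 rows)."""
    mapping: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pixel_s, word = line.split("\t")
            pixel = int(pixel_s)
            if pixel in mapping:
                raise ValueError(f"duplicate pixel {pixel} in {path}")
            mapping[pixel] = _check_word(word)
    if sorted(mapping) != list(range(256)):
        raise ValueError(f"{path} does not cover pixels 0..255 exactly")
    return Codebook(
        words=tuple(mapping[p] for p in range(256)),
        d_min=d_min,
        gc_target=gc_target,
        name=name or str(path),
    )
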