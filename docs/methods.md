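# Methods

This note documents the model implemented by `dnacipher`, the parameters
that matter, the numerical conventions that make ciphertexts reproducible
bit-for-bit, the design decisions taken where the architecture left real
choices, and the limitations we have measured.

## Codeword design and certification

The coding layer maps each 8-bit pixel value to a DNA octamer. Reliability
of any hybridization-based readout degrades when distinct strands are too
similar (false positives) or when melting temperatures are uneven. The
three constraints certified by `validate_code_set` address this:

- **SS** — the minimum Hamming distance from each word to every other word
  in the set must be at least d;
- **SC** — likewise to the *reverse complement* of every other word, so no
  codeword mimics the Watson–Crick partner of another. The self term is
  excluded: a word is allowed to resemble its own reverse complement.
  (Practical strand design usually also constrains self-complementarity to
  avoid hairpins; we keep the self term out of scope because the codebook
  here is a software error-correction object, not a wet-lab library.)
- **GC** — exactly 50% G/C per word (4 of 8 bases), an equality rather
  than a band, which keeps the candidate space cleanly enumerable
  (C(8,4)·2⁸ = 17 920 octamers).

With d = 3 the correction radius is ⌊(d−1)/2⌋ = 1: every single-base
mutant of a codeword decodes uniquely back to it. The radius is always
*derived* from the codebook's certified d_min, never assumed.

**The designer.** `design_code_set` is a seeded stochastic greedy search:
shuffle the GC-balanced candidates with a seeded generator, accept a word
iff it keeps SS ≥ d and SC ≥ d against everything accepted (one
vectorized distance scan per candidate; H(u, rc(v)) = H(v, rc(u)), so one
orientation suffices per pair), restart with a fresh shuffle on a stall,
keep the best sweep. Greedy sweeps reliably exceed 300 octamers at d = 3,
comfortably above the 256 needed; the search makes no optimality claim —
exact maximum-set construction is a hard combinatorial problem and not the
point here. Failure to reach the target raises an error carrying the best
size found (e.g. at n = 2, d = 1, GC = 50% the true capacity is 4, because
the eight balanced 2-mers form four reverse-complement pairs and SC
forbids both members of a pair).

**The packaged table.** `data/table2.tsv` ships the 50 published
pixel↦octamer assignments (pixels 0–49), checksummed against silent
corruption; they re-certify at d = 3, GC = 50% (minimum pairwise SS and SC
both equal 3). `table2_codebook()` extends them to 256 entries with the
greedy designer under a fixed internal seed, so the printed entries keep
their positions. The published worked example of single-base correction
uses the octamer `GCCTATCT`, which does not occur among the 50 printed
entries but is compatible with them (SS = 3, SC = 4, GC = 50%); we pin it
deterministically at pixel 50 so the worked example — `GCCTATCT` decodes
exactly, its corruption `GCGTATCT` strict-decodes to the sentinel and
error-corrects back — is reproducible on the packaged codebook.

## The cipher

Encryption of an H×W image under a 16-byte key:

1. **Relating key.** Every key byte is XORed with every pixel:
   `relating_key[j] = key[j] XOR X`, where X is the XOR fold of all
   pixels. This makes all sixteen bytes — and therefore all four chaotic
   parameters — depend on every pixel. We considered the alternative of
   folding pixels into the key bytewise (flat index mod 16), which
   preserves more plaintext information in the digest; we rejected it
   after measurement, because a one-pixel change then reaches only one of
   the four chaotic parameters and the unchanged logistic map leaks
   coinciding cipher pixels through the permutation (see *Limitations*),
   capping NPCR near 97.6% instead of the ideal 99.61%.
2. **Parameters.** The relating key's four 4-byte parts, read big-endian
   as integers v, give μ = 3.9 + 0.1·v/(2³²−1) for the two map parameters
   (hitting 3.9 and 4.0 exactly at the byte extremes) and
   x₀ = (v+1)/(2³²+2) for the two initial values (strictly inside (0,1)).
3. **Orbits.** Each logistic map x ← μx(1−x) is burned in for 100
   iterations, then iterated once per pixel it serves: the first map
   covers ⌈n/2⌉ pixels (row-major), the second the rest. Double precision
   throughout. An iterate that hits 0 or 1 exactly (e.g. μ = 4, x₀ = 0.5)
   would collapse the orbit; this raises a typed error and the key
   schedule retries after nudging x₀ by one representable step.
4. **Permutation.** Stable ascending argsort of the concatenated orbit
   values; output flat pixel k takes input flat pixel perm[k] (gather
   convention, row-major). Ties break by original index. Relocation only —
   the histogram is untouched.
5. **Diffusion.** Each permuted pixel is XORed with its keystream byte
   ⌊x·10¹⁴⌋ mod 256 — deep-mantissa digits of the same orbit values, so
   nearby orbit values still yield decorrelated bytes. (Note that "nice"
   values quantize unspectacularly: x = 0.5 gives byte 0, since 5·10¹³ is
   divisible by 256.)
6. **DNA encoding.** Each cipher pixel becomes its codeword; the result is
   a row-major grid of octamers.

Decryption needs the relating key, which depends on the plaintext. The
cipher container therefore stores the one-byte plaintext fold X, and the
decryptor reconstructs `relating_key = key XOR X`. We deliberately do
*not* store the relating key itself: the relating key alone determines the
keystream and permutation, so storing it would let anyone decrypt without
the secret key and would void key sensitivity at the decryption side.
Storing X leaks one byte derived from the plaintext histogram parity —
negligible next to what a pixel-wise XOR keystream already implies — and
keeps decryption key-dependent: a wrong key yields ~97–99% wrong pixels.

The classic eight 2-bit coding rules (A/T and C/G mapped to
bitwise-complementary pairs, pixel bytes split most-significant pair
first) are included as the baseline coding without redundancy; they take
no part in the error-correcting pipeline.

## Error channel and correction

`inject_errors` models substitution errors: distinct codeword positions
sampled without replacement, one uniformly chosen base position each,
replaced by a uniformly chosen different base — every corrupted word ends
at Hamming distance exactly 1 from its original. Insertions, deletions and
context-dependent error rates are out of scope.

`correct_word` decodes: exact codebook hit → `exact`; otherwise, if
exactly one codeword lies within the correction radius → `corrected`;
otherwise → the sentinel pixel 255, `fallback`. Ties inside the radius are
impossible for radius 1 with d_min = 3 but are handled defensively. The
sentinel deliberately collides with the legitimate pixel value 255; the
`ErrorReport`, not the pixel grid, is the authoritative record of
fallbacks. A word corrupted at two positions is beyond the radius and
*usually* falls back, but can legitimately land within distance 1 of a
different codeword and be miscorrected — that is the expected behaviour of
minimum-distance decoding beyond its radius, not a defect.

`correct_cipher` rewrites every correctable word to its codeword (hash
lookup for the exact majority, one vectorized distance scan for the
misses) and is idempotent.

## Security statistics

- NPCR and UACI are computed on the cipher *pixel* grids (after diffusion,
  before DNA encoding), where their definitions operate. Ideal values for
  independent uniform 8-bit ciphers: NPCR (1−1/256)·100 ≈ 99.61%, UACI
  ≈ 33.46%.
- The differential experiment draws, per trial, a fresh uniform-random
  256×256 image and a fresh pixel position, perturbs that pixel by +1 mod
  256, encrypts both images under the same key and averages over ten
  trials. Measured: NPCR ≈ 99.62%, UACI ≈ 33.47%.
- Adjacent-pixel correlation uses the discrete Pearson formulas with
  divisor N over a seeded uniform sample of adjacent pairs (1000 by
  default; horizontal, vertical and diagonal (+1,+1) offsets). At 1000
  pairs the estimator's standard deviation under zero true correlation is
  ≈ 0.032 — bounds tighter than ~0.1 should be checked with larger
  samples, which is what the acceptance test does (20 000 pairs).
- Key sensitivity encrypts the same image under a key and under the key
  with its last byte incremented (mod 256) and reports the NPCR-style
  difference of the cipher pixel grids.
- Key space: 256¹⁶ = 2¹²⁸ exactly, computed in arbitrary precision.

## Synthetic images

Three seeded generators stand in for natural test photographs, so the full
evaluation runs offline: `uniform_random` (ideal cipher-like noise),
`smooth_gradient` (a deterministic 0→255 ramp, maximal structure), and
`correlated_texture` — Gaussian-smoothed white noise, linearly requantized
to [0, 255], with the kernel width bisected until the measured horizontal
neighbour correlation lands within ±0.05 of the target (default 0.92,
the range natural photographs occupy, roughly 0.89–0.97). The textures
reproduce the second-order statistic that matters for the correlation
analysis; they do not reproduce edges, occlusions or the heavy-tailed
gradient statistics of real photographs, so passing tests speak to the
cipher's statistical behaviour, not to perceptual security on any
particular photograph.

## Problem sizes and determinism

The statistical experiments use 256×256 images and ten trials — the
conditions at which the headline numbers are defined; unit tests use
smaller images where the property under test is size-free. All stochastic
components (designer, generators, error channel, trial structure) are
driven by explicit seeds through `numpy.random.default_rng`, and the
chaotic pipeline is deterministic given (key, image). Reproducibility of
double-precision logistic iteration across platforms/compilers is assumed;
it holds for IEEE-754 arithmetic evaluated in order, but is a known risk
if an implementation re-associates floating-point operations.

## Known limitations

- **Key sensitivity is structurally below the differential statistics.** A
  one-byte key change moves exactly one of the four chaotic parameters
  (the four-part derivation localizes each byte), so one logistic map's
  orbit is unchanged. Its half of the keystream is then identical, and its
  values retain their relative order in the global sort; wherever a value
  keeps its exact global rank, the cipher pixel coincides. The collision
  rate is driven by value clustering in the unchanged orbit (the logistic
  invariant density's square-root singularities, and near-periodic windows
  of μ ∈ [3.9, 4]): measured over ten 256×256 trials, the mean one-byte
  key-sensitivity difference is ≈ 98.0% (per-trial range ≈ 88–99.7%),
  short of the ≈ 99.6% that full reseeding would give. Plaintext
  sensitivity does not suffer from this because the relating-key fold
  reaches all four parameters. Fixing key sensitivity would require mixing
  all sixteen relating-key bytes into every parameter, which the four-part
  key schedule deliberately does not do.
- **One-round, XOR-only diffusion.** Cipher pixels depend on the plaintext
  only through the permutation source and the relating key; there is no
  ciphertext chaining. This is the modelled architecture, not a
  recommendation: none of this package constitutes a vetted cryptographic
  design, and no formal security claims are made.
- **The plaintext digest in the container** (one byte) means two plaintexts
  with equal XOR fold produce the same keystream under the same key.
- **Error model.** Only substitutions, uniform over positions and bases,
  at most one per codeword in the calibrated experiment; 1000 errors on a
  65 536-word cipher corrupt ~1.5% of words. Beyond-radius corruption
  degrades to sentinels or miscorrections as described above.
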