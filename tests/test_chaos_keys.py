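"""Key schedule, logistic orbits, keystream and permutation derivation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnacipher import chaos_keys
from dnacipher.chaos_keys import (
    DegenerateOrbitError,
    derive_relating_key,
    keystream_bytes,
    logistic_orbit,
    params_from_relating_key,
    parse_key,
    permutation_from_orbits,
)


class TestRelatingKey:
    def test_all_zero_image_leaves_key_unchanged(self):
        key = bytes(range(16))
        img = np.zeros((4, 4), dtype=np.uint8)
        assert derive_relating_key(key, img) == key

    def test_every_byte_is_xored_with_the_pixel_fold(self):
        key = bytes(16)
        img = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        fold = 1 ^ 2 ^ 3 ^ 4
        assert derive_relating_key(key, img) == bytes([fold] * 16)

    def test_single_pixel_change_alters_every_byte(self):
        key = bytes(range(16))
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        img2 = img.copy()
        img2[3, 3] ^= 0x10
        a = derive_relating_key(key, img)
        b = derive_relating_key(key, img2)
        assert all(x != y for x, y in zip(a, b))

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            derive_relating_key(bytes(16), np.empty((0, 0), dtype=np.uint8))


class TestParams:
    def test_zero_part_hits_lower_mu_endpoint(self):
        p = params_from_relating_key(bytes(16))
        assert p.mu1 == 3.9
        assert p.mu2 == 3.9

    def test_ff_part_hits_upper_mu_endpoint(self):
        p = params_from_relating_key(bytes([0xFF] * 16))
        assert p.mu1 == 4.0
        assert p.mu2 == 4.0

    def test_initial_values_stay_in_open_interval(self):
        lo = params_from_relating_key(bytes(16))
        hi = params_from_relating_key(bytes([0xFF] * 16))
        assert lo.x1_0 == 1 / (2**32 + 2)
        assert 0.0 < lo.x1_0 < hi.x1_0 < 1.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            params_from_relating_key(bytes(15))

    def test_one_key_bit_flips_some_parameter(self):
        key = bytes(range(16))
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        base = params_from_relating_key(derive_relating_key(key, img))
        for byte in (0, 5, 10, 15):
            key2 = bytearray(key)
            key2[byte] ^= 0x01
            other = params_from_relating_key(derive_relating_key(bytes(key2), img))
            assert other != base


class TestLogisticOrbit:
    def test_first_iterate_mu4(self):
        orbit = logistic_orbit(4.0, 0.25, burn_in=0, length=1)
        assert orbit[0] == pytest.approx(0.75)

    def test_first_iterate_mu39(self):
        orbit = logistic_orbit(3.9, 0.5, burn_in=0, length=1)
        assert orbit[0] == pytest.approx(0.975)

    def test_degenerate_start_raises(self):
        # mu=4, x0=0.5 maps to exactly 1.0 and would collapse to 0
        with pytest.raises(DegenerateOrbitError):
            logistic_orbit(4.0, 0.5, burn_in=0, length=4)

    def test_safe_orbit_recovers_by_one_ulp_perturbation(self):
        orbit = chaos_keys._safe_orbit(4.0, 0.5, burn_in=0, length=8)
        assert orbit.shape == (8,)
        assert np.all((orbit > 0) & (orbit < 1))

    def test_values_stay_in_open_interval_after_burn_in(self):
        orbit = logistic_orbit(3.97, 0.123, burn_in=100, length=500)
        assert orbit.shape == (500,)
        assert np.all((orbit > 0) & (orbit < 1))

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            logistic_orbit(3.5, 0.3, 0, 1)
        with pytest.raises(ValueError):
            logistic_orbit(3.95, 0.0, 0, 1)


class TestKeystream:
    def test_quantizer_against_integer_arithmetic(self):
        # floor(x * 1e14) mod 256 checked by exact integer arithmetic for
        # values whose product is exactly representable
        for x in (0.5, 0.25, 0.75):
            expected = (int(x * 4) * 10**14 // 4) % 256
            got = keystream_bytes(np.array([x]), np.array([]))[0]
            assert got == expected
        assert keystream_bytes(np.array([0.5]), np.array([]))[0] == 0

    def test_empty_orbits_give_empty_keystream(self):
        assert keystream_bytes(np.array([]), np.array([])).size == 0

    def test_bytes_in_range_and_deterministic(self):
        o = logistic_orbit(3.99, 0.2, 100, 1000)
        a = keystream_bytes(o[:500], o[500:])
        b = keystream_bytes(o[:500], o[500:])
        assert np.array_equal(a, b)
        assert a.dtype == np.uint8

    def test_byte_histogram_is_roughly_uniform(self):
        """Chi-square of the keystream byte histogram over 1e5 samples stays
        below a generous bound (sanity check, not a cryptographic claim)."""
        o = logistic_orbit(3.9999, 0.3141592653589793, 100, 100_000)
        ks = keystream_bytes(o, np.array([]))
        counts = np.bincount(ks, minlength=256)
        expected = ks.size / 256
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        # df = 255: mean 255, sd ~ 22.6; allow ~6 sd
        assert chi2 < 400


class TestPermutation:
    def test_argsort_example(self):
        perm = permutation_from_orbits(np.array([0.3, 0.1]), np.array([0.2]), 3)
        assert perm.tolist() == [1, 2, 0]

    def test_sorted_orbit_gives_identity(self):
        perm = permutation_from_orbits(np.array([0.1, 0.2]), np.array([0.3]), 3)
        assert perm.tolist() == [0, 1, 2]

    def test_ties_break_by_original_index(self):
        perm = permutation_from_orbits(np.array([0.5, 0.5]), np.array([0.1]), 3)
        assert perm.tolist() == [2, 0, 1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            permutation_from_orbits(np.array([0.1]), np.array([0.2]), 3)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=1, max_value=500), st.integers(0, 2**31 - 1))
    def test_output_is_always_a_bijection(self, n, seed):
        rng = np.random.default_rng(seed)
        o = rng.random(n)
        n1 = (n + 1) // 2
        perm = permutation_from_orbits(o[:n1], o[n1:], n)
        assert np.array_equal(np.sort(perm), np.arange(n))


class TestParseKey:
    def test_hex_key(self):
        assert parse_key("000102030405060708090a0b0c0d0e0f") == bytes(range(16))

    def test_ascii_key_is_zero_padded(self):
        key = parse_key("123456789012345")
        assert len(key) == 16
        assert key == b"123456789012345\x00"

    def test_long_ascii_key_is_truncated(self):
        assert parse_key("x" * 20) == b"x" * 16
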