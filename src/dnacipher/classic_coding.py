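"""The eight classic 2-bit DNA coding rules.

Each rule is a bijection between the four bases and the four 2-bit strings
that respects base-pair complementarity: A/T receive bitwise-complementary
pairs, as do C/G. A pixel byte is rendered most-significant pair first, so
65 = 0b01000001 splits into 01|00|00|01 and becomes ``ACCA`` under rule 1.

These rules carry no redundancy — any substitution decodes to a wrong but
valid pixel — and serve only as the non-error-correcting baseline against
which the constraint-designed codebook is compared.
"""

from __future__ import annotations

__all__ = ["RULES", "classic_decode", "classic_encode"]

# rule id -> base -> 2-bit string
RULES: dict[int, dict[str, str]] = {
    1: {"A": "01", "T": "10", "C": "00", "G": "11"},
    2: {"A": "01", "T": "10", "C": "11", "G": "00"},
    3: {"A": "00", "T": "11", "C": "01", "G": "10"},
    4: {"A": "00", "T": "11", "C": "10", "G": "01"},
    5: {"A": "10", "T": "01", "C": "00", "G": "11"},
    6: {"A": "10", "T": "01", "C": "11", "G": "00"},
    7: {"A": "11", "T": "00", "C": "01", "G": "10"},
    8: {"A": "11", "T": "00", "C": "10", "G": "01"},
}

_INVERSE: dict[int, dict[str, str]] = {
    rule: {bits: base for base, bits in mapping.items()}
    for rule, mapping in RULES.items()
}


def _get_rule(rule: int) -> dict[str, str]:
    try:
        return RULES[rule]
    except KeyError:
        raise ValueError(f"rule must be 1..8, got {rule}") from None


def classic_encode(pixel: int, rule: int = 1) -> str:
    """Encode a pixel byte as a 4-base word under one of the eight rules."""
    pixel = int(pixel)
    if not 0 <= pixel <= 255:
        raise ValueError(f"pixel {pixel} out of range [0, 255]")
    _get_rule(rule)
    inverse = _INVERSE[rule]
    bits = format(pixel, "08b")
    return "".join(inverse[bits[i : i + 2]] for i in range(0, 8, 2))


def classic_decode(word: str, rule: int = 1) -> int:
    """Exact inverse of :func:`classic_encode`."""
    mapping = _get_rule(rule)
    w = word.upper()
    if len(w) != 4 or any(b not in mapping for b in w):
        raise ValueError(f"{word!r} is not a 4-base word over ACGT")
    bits = "".join(mapping[b] for b in w)
    return int(bits, 2)
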