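"""Amino-acid alphabet shared across modules."""

# the 20 standard residues, alphabetical one-letter order
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# ambiguity / non-standard codes tolerated in real input databases:
# B (D/N), J (I/L), X (any), Z (E/Q), U (selenocysteine)
AMBIGUOUS_AA = "BJXZU"

EXTENDED_AA = STANDARD_AA + AMBIGUOUS_AA


def validate_sequence(seq: str, allow_ambiguous: bool = True) -> None:
    """Raise ValueError on an empty sequence or characters outside the
    (optionally extended) uppercase amino-acid alphabet."""
    if not seq:
        raise ValueError("empty sequence")
    allowed = set(EXTENDED_AA if allow_ambiguous else STANDARD_AA)
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"invalid residue(s) {sorted(bad)!r} in sequence "
            f"(uppercase {'extended' if allow_ambiguous else 'standard'} "
            "amino-acid alphabet required)"
        )
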