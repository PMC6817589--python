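"""Shared vocabulary: the canonical amino-acid alphabet, assay labels, errors.

Everything downstream works on uppercase one-letter codes for the 20
canonical amino acids; the ambiguity/rare codes (B, J, O, U, X, Z) are never
scored and are rejected or skipped with an explicit count wherever they can
appear.
"""

from __future__ import annotations

import enum

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters that appear in real protein databases but are never scored.
NON_CANONICAL: frozenset[str] = frozenset("BJOUXZ")


class Assay(str, enum.Enum):
    """The three cell-based read-outs of TCR recognition."""

    BINDING = "binding"
    ACTIVATION = "activation"
    KILLING = "killing"

    @classmethod
    def coerce(cls, value: "Assay | str") -> "Assay":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValidationError(
                f"unknown assay label {value!r}; expected one of "
                f"{[a.value for a in cls]}"
            ) from None


class FormatError(ValueError):
    """A file does not conform to its declared dialect/schema."""


class ParseError(ValueError):
    """A field inside an otherwise well-formed file cannot be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class DegenerateNormalizationError(ValueError):
    """The epitope's background-corrected signal is not positive, so
    normalization to the epitope is undefined."""


def check_peptide(peptide: str, *, context: str = "peptide") -> str:
    """Validate that *peptide* is a non-empty uppercase canonical sequence."""
    if not peptide:
        raise ValidationError(f"{context} is empty")
    for ch in peptide:
        if ch not in AA_INDEX:
            raise ValidationError(
                f"{context} {peptide!r} contains non-canonical or lowercase "
                f"residue {ch!r}"
            )
    return peptide
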