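"""Replacement-library generation, PWM peptide scoring, Hamming distance.

The score of a query peptide under a PWM is the sum of matrix values for
its residues at the scored (non-anchor) positions, normalized by the
maximum possible score (100 per scored position), so the epitope always
scores exactly 1 and every peptide lands in [0, 1].  Anchor residues never
contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .core import AA_INDEX, AMINO_ACIDS, ValidationError, check_peptide
from .fingerprint import AssayScoreTriplet, PositionWeightMatrix

#: The wild-type epitope used as the reporting reference for edit distances.
#: The scanned (anchor-optimized) epitope carries V at P9 instead; the two
#: are distinct configuration fields throughout.
DEFAULT_HAMMING_REFERENCE = "SLLMWITQC"


def generate_replacement_library(
    epitope: str, anchor_positions: set[int] | frozenset[int]
) -> list[str]:
    """The epitope plus every single-residue variant at non-anchor positions.

    For a 9-mer with two anchors this is 7·19 + 1 = 134 peptides.  Order is
    deterministic: epitope first, then position-major with residues
    alphabetical.
    """
    check_peptide(epitope, context="epitope")
    k = len(epitope)
    anchors = {int(p) for p in anchor_positions}
    if not anchors <= set(range(1, k + 1)):
        raise ValidationError(f"anchor positions {sorted(anchors)} out of range 1..{k}")
    library = [epitope]
    for pos in range(1, k + 1):
        if pos in anchors:
            continue
        for aa in AMINO_ACIDS:
            if aa == epitope[pos - 1]:
                continue
            library.append(epitope[: pos - 1] + aa + epitope[pos:])
    return library


def score_peptide(pwm: PositionWeightMatrix, peptide: str) -> float:
    """Score *peptide* against *pwm*; the result lies in [0, 1].

    The denominator is the theoretical maximum (100 per scored position),
    which the epitope realizes because its residues are pinned at 100; the
    theoretical form also normalizes alanine-mode PWMs correctly.
    """
    if len(peptide) != pwm.k:
        raise ValidationError(
            f"peptide {peptide!r} length {len(peptide)} != PWM epitope length {pwm.k}"
        )
    check_peptide(peptide)
    w = pwm.weights
    total = 0.0
    for j, pos in enumerate(pwm.scored_positions):
        total += w[AA_INDEX[peptide[pos - 1]], j]
    return total / (100.0 * len(pwm.scored_positions))


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length peptides differ."""
    if len(a) != len(b):
        raise ValidationError(
            f"cannot compare sequences of different lengths ({len(a)} vs {len(b)})"
        )
    return sum(1 for x, y in zip(a, b) if x != y)


class Provenance(NamedTuple):
    """Where a peptide occurs in a source protein (1-based start)."""

    protein_id: str
    gene_symbol: str | None
    start: int


@dataclass(frozen=True)
class ScoredPeptide:
    """A peptide with per-assay scores, affinity, provenance and edit distance."""

    sequence: str
    scores: AssayScoreTriplet
    ic50_nm: float | None = None
    provenance: tuple[Provenance, ...] = ()
    hamming_to_reference: int | None = None

    def __post_init__(self) -> None:
        check_peptide(self.sequence)
        if self.ic50_nm is not None and not (self.ic50_nm > 0):
            raise ValidationError(f"non-positive IC50 for {self.sequence}")
        if self.hamming_to_reference is not None and not (
            0 <= self.hamming_to_reference <= len(self.sequence)
        ):
            raise ValidationError(f"impossible Hamming distance for {self.sequence}")
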