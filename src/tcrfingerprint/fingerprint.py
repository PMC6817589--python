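"""Position weight matrices from replacement-scan measurements.

A replacement scan substitutes every non-anchor position of a 9-mer epitope
with each of the 19 alternative amino acids and measures every variant in a
cell-based assay (binding, activation or killing), as percent positive
cells with a matched no-peptide background per replicate.  The PWM
("TCR fingerprint") assigns to each amino acid *a* at each scored position
*i* the normalized value

    W[a, i] = 100 * L[a, i] / L[epitope]

where L is the replicate mean of the background-corrected signal
(subtraction happens per replicate, before the mean).  Values above 100 are
trimmed to 100 and negative values are set to 0, so every cell lies on a
0-100 percent scale and the epitope's own residues are pinned at 100.
Anchor positions (P2 and P9 for HLA-A*02:01 9-mers) face the MHC groove,
are held fixed in the scan, and are not stored in the matrix at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .core import (
    AA_INDEX,
    AMINO_ACIDS,
    Assay,
    DegenerateNormalizationError,
    ValidationError,
    check_peptide,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .scan_io import MeasurementSet

logger = logging.getLogger(__name__)


def scored_positions_for(epitope: str, anchor_positions: frozenset[int] | set[int]) -> tuple[int, ...]:
    """The ordered non-anchor (scored) positions, 1-based."""
    k = len(epitope)
    anchors = set(anchor_positions)
    if not anchors <= set(range(1, k + 1)):
        raise ValidationError(f"anchor positions {sorted(anchors)} out of range 1..{k}")
    return tuple(i for i in range(1, k + 1) if i not in anchors)


@dataclass(frozen=True, eq=False)
class PositionWeightMatrix:
    """20 amino acids × scored positions, values on a 0-100 percent scale.

    ``weights[AA_INDEX[a], j]`` is W for amino acid ``a`` at scored position
    ``scored_positions[j]``.  Anchor columns are never stored.
    """

    epitope: str
    anchor_positions: frozenset[int]
    scored_positions: tuple[int, ...]
    weights: np.ndarray = field(repr=False)
    assay: str = "combined-source"
    metadata: Mapping[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        check_peptide(self.epitope, context="epitope")
        object.__setattr__(self, "anchor_positions", frozenset(int(p) for p in self.anchor_positions))
        expected = scored_positions_for(self.epitope, self.anchor_positions)
        if tuple(self.scored_positions) != expected:
            raise ValidationError(
                f"scored positions {self.scored_positions} do not complement "
                f"anchors {sorted(self.anchor_positions)} for a {len(self.epitope)}-mer"
            )
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (20, len(self.scored_positions)):
            raise ValidationError(
                f"weights shape {w.shape} != (20, {len(self.scored_positions)})"
            )
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite PWM entry")
        if w.min() < 0 or w.max() > 100:
            raise ValidationError("PWM entries must lie in [0, 100]")
        for j, pos in enumerate(self.scored_positions):
            aa = self.epitope[pos - 1]
            if w[AA_INDEX[aa], j] != 100.0:
                raise ValidationError(
                    f"epitope residue {aa} at position {pos} must weigh exactly 100"
                )
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    # -- access ------------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.epitope)

    def column_index(self, position: int) -> int:
        try:
            return self.scored_positions.index(position)
        except ValueError:
            raise KeyError(f"position {position} is not scored (anchors: "
                           f"{sorted(self.anchor_positions)})") from None

    def weight(self, amino_acid: str, position: int) -> float:
        return float(self.weights[AA_INDEX[amino_acid], self.column_index(position)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionWeightMatrix):
            return NotImplemented
        return (
            self.epitope == other.epitope
            and self.anchor_positions == other.anchor_positions
            and self.scored_positions == other.scored_positions
            and self.assay == other.assay
            and np.array_equal(self.weights, other.weights)
        )

    def __hash__(self) -> int:  # frozen dataclass with eq=False would inherit id-hash
        return hash((self.epitope, self.anchor_positions, self.assay))

    def allclose(self, other: "PositionWeightMatrix", atol: float = 1e-9) -> bool:
        return (
            self.epitope == other.epitope
            and self.anchor_positions == other.anchor_positions
            and np.allclose(self.weights, other.weights, atol=atol)
        )


# ---------------------------------------------------------------------------
# construction from measurements
# ---------------------------------------------------------------------------

def _substitution_of(variant: str, epitope: str, anchors: frozenset[int]) -> tuple[str, int]:
    """Identify the single substitution (residue, 1-based position) of *variant*."""
    diffs = [i + 1 for i in range(len(epitope)) if variant[i] != epitope[i]]
    if len(diffs) != 1:
        raise ValidationError(
            f"peptide {variant} differs from epitope {epitope} at "
            f"{len(diffs)} positions; expected exactly 1"
        )
    pos = diffs[0]
    if pos in anchors:
        raise ValidationError(
            f"peptide {variant} substitutes anchor position {pos}"
        )
    return variant[pos - 1], pos


def build_pwm(
    measurements: "MeasurementSet",
    assay: Assay | str,
    epitope: str,
    anchor_positions: set[int] | frozenset[int],
    *,
    on_missing: str = "impute",
) -> PositionWeightMatrix:
    """Build the per-assay PWM from replacement-scan measurements.

    For each single-substitution variant (residue *a* at scored position
    *i*), W[a, i] = 100 · L[a, i] / L[epitope], with L the mean over
    replicates of (signal − background), clamped to [0, 100].  The
    epitope's own residue at every scored position is set to 100.

    ``on_missing`` controls cells with no measurement: ``"impute"`` sets
    them to 0 with a logged warning (conservative: unmeasured means not
    recognized), ``"error"`` raises.
    """
    assay = Assay.coerce(assay)
    check_peptide(epitope, context="epitope")
    anchors = frozenset(int(p) for p in anchor_positions)
    positions = scored_positions_for(epitope, anchors)
    if on_missing not in ("impute", "error"):
        raise ValueError(f"on_missing must be 'impute' or 'error', got {on_missing!r}")

    epi_reps = measurements.replicates(epitope, assay)
    if not epi_reps:
        raise ValidationError(
            f"no {assay.value} measurements for epitope {epitope}"
        )
    l_epitope = float(np.mean([r.corrected for r in epi_reps]))
    if l_epitope <= 0:
        raise DegenerateNormalizationError(
            f"epitope {epitope} background-corrected mean is {l_epitope:.4g} "
            f"in {assay.value}; cannot normalize"
        )

    col = {p: j for j, p in enumerate(positions)}
    weights = np.full((20, len(positions)), np.nan)
    for peptide in measurements.peptides(assay):
        if peptide == epitope:
            continue
        if len(peptide) != len(epitope):
            raise ValidationError(
                f"peptide {peptide} length {len(peptide)} != epitope length {len(epitope)}"
            )
        residue, pos = _substitution_of(peptide, epitope, anchors)
        reps = measurements.replicates(peptide, assay)
        l_var = float(np.mean([r.corrected for r in reps]))
        w = 100.0 * l_var / l_epitope
        weights[AA_INDEX[residue], col[pos]] = min(100.0, max(0.0, w))

    for pos in positions:
        weights[AA_INDEX[epitope[pos - 1]], col[pos]] = 100.0

    n_missing = int(np.isnan(weights).sum())
    if n_missing:
        if on_missing == "error":
            raise ValidationError(
                f"{n_missing} unmeasured PWM cell(s) in {assay.value} assay"
            )
        logger.warning(
            "%s assay: %d unmeasured PWM cell(s) imputed as 0 (not recognized)",
            assay.value, n_missing,
        )
        weights = np.nan_to_num(weights, nan=0.0)

    return PositionWeightMatrix(
        epitope=epitope,
        anchor_positions=anchors,
        scored_positions=positions,
        weights=weights,
        assay=assay.value,
    )


# ---------------------------------------------------------------------------
# PWM comparison and score fusion
# ---------------------------------------------------------------------------

def pwm_similarity(a: PositionWeightMatrix, b: PositionWeightMatrix) -> float:
    """Pearson correlation over the paired 20×|P| cell vectors.

    Both matrices must share epitope length, anchors and scored positions.
    Returns NaN if either matrix is constant (zero variance).
    """
    if (a.k != b.k or a.anchor_positions != b.anchor_positions
            or a.scored_positions != b.scored_positions):
        raise ValidationError("PWMs have mismatched dimensions/anchors")
    x = a.weights.ravel()
    y = b.weights.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class AssayScoreTriplet:
    """Per-assay peptide scores and their mean, each in [0, 1]."""

    binding: float
    activation: float
    killing: float
    combined: float

    def __post_init__(self) -> None:
        for name in ("binding", "activation", "killing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} score {v} outside [0, 1]")


def combine_scores(binding: float, activation: float, killing: float) -> AssayScoreTriplet:
    """Fuse per-assay peptide scores into the overall TCR recognition score
    (the arithmetic mean of the three)."""
    return AssayScoreTriplet(
        binding=float(binding),
        activation=float(activation),
        killing=float(killing),
        combined=(float(binding) + float(activation) + float(killing)) / 3.0,
    )


# ---------------------------------------------------------------------------
# alanine-scan adaptation
# ---------------------------------------------------------------------------

def build_alanine_pwm(
    alanine_values: Mapping[int, float],
    epitope: str,
    anchor_positions: set[int] | frozenset[int],
    permissive_threshold: float = 0.5,
) -> PositionWeightMatrix:
    """Adapt an alanine scan (alanine-only substitutions) into a scoreable PWM.

    ``alanine_values`` maps each non-anchor position to the normalized
    alanine-substitution value (fraction of the epitope signal, in [0, 1]).
    Positions whose value reaches ``permissive_threshold`` are treated as
    permissive — any residue is tolerated there (all 20 rows get 100).
    Non-permissive positions keep only the epitope residue at 100 and
    alanine at 100·value; every other residue gets 0.
    """
    check_peptide(epitope, context="epitope")
    anchors = frozenset(int(p) for p in anchor_positions)
    positions = scored_positions_for(epitope, anchors)
    if not (0.0 < permissive_threshold <= 1.0):
        raise ValidationError(
            f"permissive_threshold {permissive_threshold} outside (0, 1]"
        )
    missing = [p for p in positions if p not in alanine_values]
    if missing:
        raise ValidationError(f"missing alanine value for position(s) {missing}")

    weights = np.zeros((20, len(positions)))
    for j, pos in enumerate(positions):
        value = float(alanine_values[pos])
        if not (0.0 <= value <= 1.0):
            raise ValidationError(
                f"alanine value {value} at position {pos} outside [0, 1]"
            )
        if value >= permissive_threshold:
            weights[:, j] = 100.0
        else:
            weights[AA_INDEX["A"], j] = 100.0 * value
            weights[AA_INDEX[epitope[pos - 1]], j] = 100.0
    return PositionWeightMatrix(
        epitope=epitope,
        anchor_positions=anchors,
        scored_positions=positions,
        weights=weights,
        assay="alanine-scan",
    )
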