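"""Proteome-wide off-target screening against a TCR fingerprint.

Enumerates every k-mer window of a proteome (with provenance, deduplicated
at the sequence level — a peptide's score depends only on its sequence),
keeps predicted MHC binders (IC50 at or below the cutoff, 500 nM by
default), scores each candidate under the three per-assay PWMs, ranks by
the combined recognition score, bins the score distribution into motif
matrices, and annotates hits with normal-tissue RNA expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import AA_INDEX, AMINO_ACIDS, Assay, ValidationError
from .fingerprint import PositionWeightMatrix, combine_scores
from .scoring import Provenance, ScoredPeptide, hamming_distance, score_peptide

logger = logging.getLogger(__name__)

DEFAULT_IC50_MAX_NM = 500.0
#: Five score bins; the lowest and highest match the printed motif-analysis
#: groups 0.25-0.4 and 0.85-1.
DEFAULT_BIN_EDGES = (0.25, 0.40, 0.55, 0.70, 0.85, 1.00)
DEFAULT_TPM_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# k-mer enumeration
# ---------------------------------------------------------------------------

@dataclass
class KmerIndex:
    """Deduplicated peptide → provenance index over a proteome."""

    k: int
    peptides: dict[str, list[Provenance]]
    n_windows_total: int
    n_windows_skipped: int

    @property
    def n_windows_emitted(self) -> int:
        return self.n_windows_total - self.n_windows_skipped

    def __len__(self) -> int:
        return len(self.peptides)


def enumerate_kmers(proteins: Iterable, k: int) -> KmerIndex:
    """Enumerate every canonical length-*k* window with provenance.

    Windows containing non-canonical residues are skipped and counted.
    Duplicate sequences merge into one peptide whose provenance lists every
    (protein_id, gene_symbol, 1-based start).  Proteins are streamed; only
    the deduplicated index is held.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    index: dict[str, list[Provenance]] = {}
    n_total = 0
    n_skipped = 0
    canonical = AA_INDEX
    for protein in proteins:
        seq = protein.sequence
        n = len(seq)
        if n < k:
            continue
        n_total += n - k + 1
        # next position >= start that is non-canonical, or n if none
        next_bad = -1
        for start in range(n - k + 1):
            if next_bad < start:
                next_bad = n
                for j in range(start, n):
                    if seq[j] not in canonical:
                        next_bad = j
                        break
            if next_bad < start + k:
                n_skipped += 1
                continue
            pep = seq[start:start + k]
            index.setdefault(pep, []).append(
                Provenance(protein.protein_id, protein.gene_symbol, start + 1)
            )
    logger.info(
        "enumerated %d windows (%d skipped for non-canonical residues), "
        "%d unique %d-mers", n_total, n_skipped, len(index), k,
    )
    return KmerIndex(k=k, peptides=index, n_windows_total=n_total,
                     n_windows_skipped=n_skipped)


# ---------------------------------------------------------------------------
# affinity filter
# ---------------------------------------------------------------------------

@dataclass
class AffinityFilterResult:
    """Predicted binders plus counts of the two distinct drop reasons."""

    kept: set[str]
    n_unpredicted: int
    n_above_cutoff: int


def filter_by_affinity(
    peptides: Iterable[str], affinity, ic50_max_nm: float = DEFAULT_IC50_MAX_NM
) -> AffinityFilterResult:
    """Keep peptides with IC50 ≤ ``ic50_max_nm`` (boundary inclusive).

    Peptides absent from the affinity map are dropped and counted
    separately from above-cutoff drops (the screening universe is the
    predicted-binder set, so no prediction means no candidacy).
    """
    if not (ic50_max_nm > 0):
        raise ValidationError(f"ic50_max_nm must be positive, got {ic50_max_nm}")
    kept: set[str] = set()
    n_unpredicted = 0
    n_above = 0
    for pep in peptides:
        ic50 = affinity.get(pep)
        if ic50 is None:
            n_unpredicted += 1
        elif ic50 <= ic50_max_nm:
            kept.add(pep)
        else:
            n_above += 1
    logger.info(
        "affinity filter: kept %d, dropped %d above %.4g nM, %d unpredicted",
        len(kept), n_above, ic50_max_nm, n_unpredicted,
    )
    return AffinityFilterResult(kept=kept, n_unpredicted=n_unpredicted,
                                n_above_cutoff=n_above)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_peptides(
    peptides: Iterable[str],
    pwms: Mapping[str, PositionWeightMatrix],
    *,
    provenance: Mapping[str, Sequence[Provenance]] | None = None,
    affinity=None,
    hamming_reference: str | None = None,
) -> list[ScoredPeptide]:
    """Score peptides under the three per-assay PWMs and rank them.

    ``pwms`` must supply all of binding, activation and killing.  Sorting
    is by combined score descending, ties broken lexicographically by
    sequence, so the order is deterministic and invariant to input
    permutation.
    """
    by_assay: dict[Assay, PositionWeightMatrix] = {}
    for key, pwm in pwms.items():
        by_assay[Assay.coerce(getattr(key, "value", key))] = pwm
    missing = [a.value for a in Assay if a not in by_assay]
    if missing:
        raise ValidationError(f"missing PWM(s) for assay(s): {missing}")

    scored: list[ScoredPeptide] = []
    for pep in peptides:
        triplet = combine_scores(
            score_peptide(by_assay[Assay.BINDING], pep),
            score_peptide(by_assay[Assay.ACTIVATION], pep),
            score_peptide(by_assay[Assay.KILLING], pep),
        )
        scored.append(ScoredPeptide(
            sequence=pep,
            scores=triplet,
            ic50_nm=None if affinity is None else affinity.get(pep),
            provenance=tuple((provenance or {}).get(pep, ())),
            hamming_to_reference=(
                None if hamming_reference is None
                else hamming_distance(pep, hamming_reference)
            ),
        ))
    scored.sort(key=lambda sp: (-sp.scores.combined, sp.sequence))
    return scored


# ---------------------------------------------------------------------------
# score binning and motif matrices
# ---------------------------------------------------------------------------

@dataclass
class MotifMatrix:
    """Per-bin position frequency matrix over the full peptide length
    (anchors included — anchor preferences are informative here)."""

    bin_label: str
    lower: float
    upper: float
    k: int
    counts: np.ndarray = field(repr=False)  # (k, 20) ints, AMINO_ACIDS order
    n_peptides: int = 0

    @property
    def frequencies(self) -> np.ndarray | None:
        """Counts normalized per position; ``None`` when the bin is empty."""
        if self.n_peptides == 0:
            return None
        return self.counts / float(self.n_peptides)


def bin_and_motif(
    scored: Sequence[ScoredPeptide],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> list[MotifMatrix]:
    """Split peptides into score bins and build one motif matrix per bin.

    Bins are half-open [lo, hi) except the last, which is closed.  Peptides
    scoring outside the full edge range are excluded (counted in the log).
    """
    edges = [float(e) for e in bin_edges]
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin_edges must be strictly increasing with >= 2 values")
    if edges[0] < 0 or edges[-1] > 1:
        raise ValidationError("bin_edges must lie within [0, 1]")
    if not scored:
        k = 0
    else:
        k = len(scored[0].sequence)

    n_bins = len(edges) - 1
    motifs = [
        MotifMatrix(
            bin_label=(f"[{edges[b]:g},{edges[b + 1]:g}"
                       + ("]" if b == n_bins - 1 else ")")),
            lower=edges[b], upper=edges[b + 1], k=k,
            counts=np.zeros((k, 20), dtype=int),
        )
        for b in range(n_bins)
    ]
    n_out = 0
    for sp in scored:
        s = sp.scores.combined
        if s < edges[0] or s > edges[-1]:
            n_out += 1
            continue
        b = min(int(np.searchsorted(edges, s, side="right")) - 1, n_bins - 1)
        m = motifs[b]
        for i, aa in enumerate(sp.sequence):
            m.counts[i, AA_INDEX[aa]] += 1
        m.n_peptides += 1
    if n_out:
        logger.info("motif binning: %d peptide(s) outside [%g, %g] excluded",
                    n_out, edges[0], edges[-1])
    return motifs


# ---------------------------------------------------------------------------
# expression annotation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionAnnotation:
    """Tissue-expression summary for one peptide's source genes."""

    peptide: str
    gene_tpm: dict[str, dict[str, float]]
    max_tpm: float | None
    tissues_above: int | None
    no_expression_data: bool


def annotate_expression(
    scored: Sequence[ScoredPeptide],
    expression,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
) -> dict[str, ExpressionAnnotation]:
    """Attach normal-tissue TPM profiles to each peptide via its source genes.

    A tissue counts as "above" when any source gene exceeds ``tpm_threshold``
    TPM there.  Peptides whose genes are all absent from the table are
    flagged ``no_expression_data`` with no numeric fields.
    """
    annotations: dict[str, ExpressionAnnotation] = {}
    for sp in scored:
        genes = sorted({p.gene_symbol for p in sp.provenance if p.gene_symbol})
        gene_tpm: dict[str, dict[str, float]] = {}
        for gene in genes:
            row = expression.tpm(gene)
            if row is not None:
                gene_tpm[gene] = {t: float(v) for t, v in row.items()}
        if not gene_tpm:
            annotations[sp.sequence] = ExpressionAnnotation(
                peptide=sp.sequence, gene_tpm={}, max_tpm=None,
                tissues_above=None, no_expression_data=True,
            )
            continue
        tissues = expression.tissues
        per_tissue_max = {
            t: max(v.get(t, 0.0) for v in gene_tpm.values()) for t in tissues
        }
        annotations[sp.sequence] = ExpressionAnnotation(
            peptide=sp.sequence,
            gene_tpm=gene_tpm,
            max_tpm=max(per_tissue_max.values()) if per_tissue_max else 0.0,
            tissues_above=sum(1 for v in per_tissue_max.values() if v > tpm_threshold),
            no_expression_data=False,
        )
    return annotations
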