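"""Synthetic inputs for the whole pipeline, generated from a planted truth.

Everything the pipeline consumes can be simulated here with a known ground
truth: a recognition kernel (a true PWM with designated critical
positions), replicate replacement-scan measurements with multiplicative
noise and per-replicate background, a decoy proteome with planted
cross-reactive peptides, anchor-rule-based binding affinities, tissue
expression, and labelled activation outcomes.  Every output is a pure
function of (scenario, seed).

The defaults mirror the real study's structure: a 9-mer epitope scanned at
seven non-anchor positions (a 134-peptide library), three assays with
three replicates each, ~10% relative replicate noise, backgrounds of a few
percent positive cells, and anchor preferences (L/M at P2, V/L/C at P9)
deciding which peptides are predicted MHC binders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import AA_INDEX, AMINO_ACIDS, Assay, ValidationError, check_peptide
from .fingerprint import PositionWeightMatrix, scored_positions_for
from .scan_io import (
    MeasurementRecord,
    MeasurementSet,
    ProteinRecord,
    AffinityMap,
    ExpressionTable,
    write_affinity_table,
    write_expression_table,
    write_fasta,
    write_measurements,
)
from .scoring import generate_replacement_library, score_peptide
from .classifier import LabelledScore

DEFAULT_SEED = 20191022

# fixed sub-stream tags so independent generators never share a stream
_STREAMS = {
    "kernel": 1, "measurements": 2, "proteome": 3, "affinity": 4,
    "expression": 5, "outcomes": 6, "clamp": 7,
}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream], int(extra)])


def _noise_factors(rng: np.random.Generator, cv: float, size: int,
                   model: str = "lognormal") -> np.ndarray:
    """Multiplicative replicate noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    if model == "lognormal":
        sigma = np.sqrt(np.log1p(cv * cv))
        return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)
    if model == "gaussian":
        return 1.0 + rng.normal(0.0, cv, size=size)
    raise ValidationError(f"unknown noise model {model!r}")


@dataclass(frozen=True)
class SyntheticScenario:
    """All knobs of a synthetic study; the seed fully determines outputs."""

    seed: int = DEFAULT_SEED
    epitope: str = "SLLMWITQV"
    anchors: frozenset[int] = frozenset({2, 9})
    critical_positions: frozenset[int] = frozenset({5, 8})
    replicates: int = 3
    noise_cv: float = 0.10
    noise_model: str = "lognormal"
    background_level: float = 2.0   # mean percent positive cells, no peptide
    epitope_signal: float = 60.0    # epitope signal above background, percent
    n_proteins: int = 2000
    protein_length: int = 300
    n_planted: int = 10
    #: residues granting a low (binder-range) synthetic IC50, per anchor position
    anchor_rule: Mapping[int, str] = field(
        default_factory=lambda: {2: "LM", 9: "VLC"})
    true_cutoff: float = 0.85
    flip_rate: float = 0.0

    def __post_init__(self) -> None:
        check_peptide(self.epitope, context="epitope")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for pos, residues in self.anchor_rule.items():
            if self.epitope[pos - 1] not in residues:
                raise ValidationError(
                    f"epitope residue at P{pos} violates the anchor rule; "
                    f"planted peptides could never pass the affinity filter"
                )


# ---------------------------------------------------------------------------
# kernel and planted peptides
# ---------------------------------------------------------------------------

def make_kernel(
    seed: int,
    epitope: str,
    anchors: frozenset[int] | set[int],
    critical_positions: frozenset[int] | set[int],
) -> PositionWeightMatrix:
    """A ground-truth PWM with designated critical positions.

    Epitope residues weigh 100.  At critical positions every other residue
    weighs at most 10 (substitution abolishes recognition); at tolerant
    positions other residues draw from a broad uniform(10, 90) distribution.
    """
    check_peptide(epitope, context="epitope")
    anchors = frozenset(int(p) for p in anchors)
    critical = frozenset(int(p) for p in critical_positions)
    positions = scored_positions_for(epitope, anchors)
    if not critical <= set(positions):
        raise ValidationError(
            f"critical positions {sorted(critical)} not all scored"
        )
    rng = _rng(seed, "kernel")
    weights = np.empty((20, len(positions)))
    for j, pos in enumerate(positions):
        if pos in critical:
            weights[:, j] = rng.uniform(0.0, 10.0, size=20)
        else:
            weights[:, j] = rng.uniform(10.0, 90.0, size=20)
        weights[AA_INDEX[epitope[pos - 1]], j] = 100.0
    return PositionWeightMatrix(
        epitope=epitope,
        anchor_positions=anchors,
        scored_positions=positions,
        weights=weights,
        assay="truth-kernel",
    )


def plant_peptides(kernel: PositionWeightMatrix,
                   scenario: SyntheticScenario) -> list[tuple[str, float]]:
    """Design cross-reactive peptides from the kernel, with intended scores.

    Each planted peptide keeps the epitope residue at every critical
    position and substitutes one or two tolerant positions with the
    best-tolerated non-epitope residue there, so its kernel score stays
    high while the sequence is distinct.  Deterministic; no randomness.
    """
    tolerant = [p for p in kernel.scored_positions
                if p not in scenario.critical_positions]
    subs: dict[int, str] = {}
    for pos in tolerant:
        j = kernel.column_index(pos)
        order = np.argsort(kernel.weights[:, j])[::-1]
        for idx in order:
            if AMINO_ACIDS[idx] != kernel.epitope[pos - 1]:
                subs[pos] = AMINO_ACIDS[idx]
                break

    from itertools import combinations

    combos: list[tuple[int, ...]] = []
    for size in (1, 2, 3):
        combos.extend(combinations(tolerant, size))
        if len(combos) >= scenario.n_planted:
            break
    if len(combos) < scenario.n_planted:
        raise ValidationError(
            f"cannot design {scenario.n_planted} planted peptides from "
            f"{len(tolerant)} tolerant positions"
        )
    planted: list[tuple[str, float]] = []
    for combo in combos[: scenario.n_planted]:
        seq = list(kernel.epitope)
        for pos in combo:
            seq[pos - 1] = subs[pos]
        peptide = "".join(seq)
        planted.append((peptide, score_peptide(kernel, peptide)))
    return planted


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def simulate_measurements(kernel: PositionWeightMatrix,
                          scenario: SyntheticScenario) -> MeasurementSet:
    """Simulate the replacement-scan library for all three assays.

    Each library peptide's true signal is background + epitope_signal times
    the kernel-implied fraction; each replicate gets multiplicative noise
    at the scenario CV, and the background column is drawn per replicate
    around the background level.  With zero noise, PWM construction
    recovers the kernel exactly.
    """
    library = generate_replacement_library(kernel.epitope,
                                           kernel.anchor_positions)
    records: list[MeasurementRecord] = []
    for a_idx, assay in enumerate(Assay):
        rng = _rng(scenario.seed, "measurements", a_idx)
        for peptide in library:
            if peptide == kernel.epitope:
                fraction = 1.0
            else:
                diffs = [i for i in range(len(peptide))
                         if peptide[i] != kernel.epitope[i]]
                pos = diffs[0] + 1
                fraction = kernel.weight(peptide[pos - 1], pos) / 100.0
            true_signal = scenario.background_level + scenario.epitope_signal * fraction
            sig_noise = _noise_factors(rng, scenario.noise_cv,
                                       scenario.replicates, scenario.noise_model)
            bg_noise = _noise_factors(rng, scenario.noise_cv,
                                      scenario.replicates, scenario.noise_model)
            for r in range(scenario.replicates):
                records.append(MeasurementRecord(
                    peptide=peptide,
                    assay=assay,
                    replicate_id=f"r{r + 1}",
                    signal=float(true_signal * sig_noise[r]),
                    background=float(scenario.background_level * bg_noise[r]),
                ))
    return MeasurementSet(records)


def simulate_clamp_measurements(
    seed: int = DEFAULT_SEED,
    epitope: str = "SLLMWITQV",
    anchors: frozenset[int] | set[int] = frozenset({2, 9}),
    *,
    n_overdrive: int = 4,
    n_negative: int = 4,
    replicates: int = 3,
    noise_cv: float = 0.05,
    background_level: float = 2.0,
    epitope_signal: float = 60.0,
) -> tuple[MeasurementSet, list[str], list[str]]:
    """Stress data for the PWM clamping rules.

    ``n_overdrive`` variants get mean background-corrected signals 1.2-1.5
    times the epitope's (their raw weights would exceed 100); ``n_negative``
    variants fall below background (raw weights would be negative).  Returns
    (measurements, overdrive peptides, below-background peptides); the
    binding assay only.
    """
    anchors = frozenset(int(p) for p in anchors)
    library = generate_replacement_library(epitope, anchors)
    variants = library[1:]
    rng = _rng(seed, "clamp")
    picked = rng.choice(len(variants), size=n_overdrive + n_negative,
                        replace=False)
    overdrive = [variants[i] for i in picked[:n_overdrive]]
    negative = [variants[i] for i in picked[n_overdrive:]]

    fractions: dict[str, float] = {epitope: 1.0}
    for pep in variants:
        fractions[pep] = float(rng.uniform(0.1, 0.9))
    for pep in overdrive:
        fractions[pep] = float(rng.uniform(1.2, 1.5))
    for pep in negative:
        fractions[pep] = float(rng.uniform(-0.08, -0.05))

    records: list[MeasurementRecord] = []
    for pep in library:
        true_signal = background_level + epitope_signal * fractions[pep]
        sig_noise = _noise_factors(rng, noise_cv, replicates)
        bg_noise = _noise_factors(rng, noise_cv, replicates)
        for r in range(replicates):
            records.append(MeasurementRecord(
                peptide=pep,
                assay=Assay.BINDING,
                replicate_id=f"r{r + 1}",
                signal=max(0.0, float(true_signal * sig_noise[r])),
                background=float(background_level * bg_noise[r]),
            ))
    return MeasurementSet(records), overdrive, negative


# ---------------------------------------------------------------------------
# proteome, affinity, expression
# ---------------------------------------------------------------------------

def simulate_proteome(
    scenario: SyntheticScenario,
    planted_peptides: Sequence[str],
) -> tuple[list[ProteinRecord], dict[str, list[tuple[str, int]]]]:
    """A random-composition decoy proteome with each peptide planted once.

    The scanning epitope is always embedded in addition to the planted
    list.  Returns the proteins and a truth map peptide → [(protein_id,
    1-based start)].
    """
    k = len(scenario.epitope)
    if scenario.protein_length < k:
        raise ValidationError("protein_length shorter than the epitope")
    to_embed = [scenario.epitope] + [p for p in planted_peptides
                                     if p != scenario.epitope]
    for pep in to_embed:
        if len(pep) != k:
            raise ValidationError(f"planted peptide {pep} is not a {k}-mer")
    if len(to_embed) > scenario.n_proteins:
        raise ValidationError("more planted peptides than proteins")

    rng = _rng(scenario.seed, "proteome")
    alphabet = np.array(list(AMINO_ACIDS))
    sequences = [
        "".join(rng.choice(alphabet, size=scenario.protein_length))
        for _ in range(scenario.n_proteins)
    ]
    hosts = rng.choice(scenario.n_proteins, size=len(to_embed), replace=False)
    starts = rng.integers(0, scenario.protein_length - k + 1,
                          size=len(to_embed))
    truth: dict[str, list[tuple[str, int]]] = {}
    for pep, host, start in zip(to_embed, hosts, starts):
        seq = sequences[host]
        sequences[host] = seq[:start] + pep + seq[start + k:]
        pid = f"SYN{host:05d}"
        truth.setdefault(pep, []).append((pid, int(start) + 1))

    proteins = [
        ProteinRecord(protein_id=f"SYN{i:05d}", gene_symbol=f"GENE{i:04d}",
                      sequence=sequences[i])
        for i in range(scenario.n_proteins)
    ]
    return proteins, truth


def simulate_affinity(
    peptides,
    anchor_rule: Mapping[int, str],
    seed: int,
) -> AffinityMap:
    """Anchor-rule synthetic IC50s: rule-matching peptides draw log-uniform
    in (1, 500] nM (predicted binders), all others in (500, 50000] nM.
    Deterministic per seed and independent of input iteration order."""
    ordered = sorted(peptides)
    rng = _rng(seed, "affinity")
    u = 1.0 - rng.random(len(ordered))  # in (0, 1]
    entries: dict[str, float] = {}
    for i, pep in enumerate(ordered):
        matches = all(pep[pos - 1] in residues
                      for pos, residues in anchor_rule.items())
        if matches:
            entries[pep] = float(np.exp(u[i] * np.log(500.0)))
        else:
            entries[pep] = float(500.0 * np.exp(u[i] * np.log(100.0)))
    return AffinityMap(entries)


def simulate_expression(
    genes: Sequence[str],
    seed: int,
    n_tissues: int = 37,
    zero_fraction: float = 0.3,
) -> ExpressionTable:
    """Zero-inflated log-normal TPM profiles across normal tissues."""
    import pandas as pd

    rng = _rng(seed, "expression")
    tissues = [f"tissue_{i + 1:02d}" for i in range(n_tissues)]
    values = 10.0 ** rng.normal(0.5, 0.8, size=(len(genes), n_tissues))
    values[rng.random((len(genes), n_tissues)) < zero_fraction] = 0.0
    return ExpressionTable(pd.DataFrame(values, index=list(genes),
                                        columns=tissues))


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def simulate_outcomes(
    scored,
    true_cutoff: float,
    flip_rate: float,
    seed: int,
) -> list[LabelledScore]:
    """Labelled activation outcomes for scored peptides.

    Peptides whose combined score reaches ``true_cutoff`` activate strongly
    (normalized activation drawn in [0.85, 1.25]); the rest stay near
    baseline ([0, 0.12]).  Labels flip with probability ``flip_rate``.
    """
    if not (0.0 <= flip_rate < 0.5):
        raise ValidationError(f"flip_rate {flip_rate} outside [0, 0.5)")
    rng = _rng(seed, "outcomes")
    n = len(scored)
    flips = rng.random(n) < flip_rate
    high = rng.uniform(0.85, 1.25, size=n)
    low = rng.uniform(0.0, 0.12, size=n)
    items: list[LabelledScore] = []
    for i, sp in enumerate(scored):
        active = (sp.scores.combined >= true_cutoff) ^ bool(flips[i])
        items.append(LabelledScore.from_activation(
            peptide=sp.sequence,
            score=sp.scores.combined,
            activation_observed=float(high[i] if active else low[i]),
        ))
    return items


# ---------------------------------------------------------------------------
# full scenario bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Every pipeline input for one scenario, plus the ground truth."""

    scenario: SyntheticScenario
    kernel: PositionWeightMatrix
    planted: list[tuple[str, float]]  # (peptide, intended combined score)
    measurements: MeasurementSet
    proteins: list[ProteinRecord]
    truth: dict[str, list[tuple[str, int]]]
    affinity: AffinityMap
    expression: ExpressionTable


def make_scenario_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate the complete, internally consistent input bundle."""
    from .proteome_scan import enumerate_kmers

    kernel = make_kernel(scenario.seed, scenario.epitope, scenario.anchors,
                         scenario.critical_positions)
    planted = plant_peptides(kernel, scenario)
    measurements = simulate_measurements(kernel, scenario)
    proteins, truth = simulate_proteome(scenario, [p for p, _ in planted])
    index = enumerate_kmers(proteins, len(scenario.epitope))
    affinity = simulate_affinity(index.peptides.keys(), scenario.anchor_rule,
                                 scenario.seed)
    expression = simulate_expression([p.gene_symbol for p in proteins],
                                     scenario.seed)
    return SyntheticDataset(
        scenario=scenario, kernel=kernel, planted=planted,
        measurements=measurements, proteins=proteins, truth=truth,
        affinity=affinity, expression=expression,
    )


def write_scenario_files(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write measurements.tsv, proteome.fa, affinity.tsv, expression.tsv,
    truth.json into *outdir*; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": outdir / "measurements.tsv",
        "proteome": outdir / "proteome.fa",
        "affinity": outdir / "affinity.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    write_measurements(dataset.measurements, paths["measurements"])
    write_fasta(dataset.proteins, paths["proteome"])
    write_affinity_table(dataset.affinity, paths["affinity"])
    write_expression_table(dataset.expression, paths["expression"])
    truth = {
        "seed": dataset.scenario.seed,
        "epitope": dataset.scenario.epitope,
        "anchors": sorted(dataset.scenario.anchors),
        "critical_positions": sorted(dataset.scenario.critical_positions),
        "planted": [
            {"peptide": pep, "intended_score": round(score, 12),
             "locations": dataset.truth.get(pep, [])}
            for pep, score in dataset.planted
        ],
        "epitope_locations": dataset.truth.get(dataset.scenario.epitope, []),
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
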