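"""End-to-end pipeline: measurements → PWMs → proteome scan → ranked hits
→ motif bins → expression annotation → ROC classification.

A :class:`RunConfig` carries every threshold explicitly (nothing is
hard-coded in stage logic), is validated before any stage runs, and is
embedded verbatim in every report, so identical config + inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .core import Assay, ValidationError, check_peptide
from .classifier import (
    ClassifierResult,
    LabelledScore,
    classify,
    roc_curve,
    select_cutoff,
)
from .fingerprint import build_pwm
from .proteome_scan import (
    DEFAULT_BIN_EDGES,
    DEFAULT_IC50_MAX_NM,
    DEFAULT_TPM_THRESHOLD,
    annotate_expression,
    bin_and_motif,
    enumerate_kmers,
    filter_by_affinity,
    rank_peptides,
)
from . import scan_io
from .scoring import DEFAULT_HAMMING_REFERENCE
from .synthetic_data import (
    DEFAULT_SEED,
    SyntheticScenario,
    make_scenario_dataset,
    simulate_outcomes,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    epitope: str = "SLLMWITQV"
    hamming_reference: str = DEFAULT_HAMMING_REFERENCE
    anchors: tuple[int, ...] = (2, 9)
    ic50_max_nm: float = DEFAULT_IC50_MAX_NM
    activation_threshold: float = 0.75
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    permissive_threshold: float = 0.5
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD
    seed: int = DEFAULT_SEED
    #: named synthetic scenario ("default" or "small"); None = file inputs
    scenario: str | None = None
    measurements: str | None = None
    proteome: str | None = None
    affinity: str | None = None
    expression: str | None = None
    labels: str | None = None
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        for name in ("anchors", "bin_edges"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def validate(self) -> None:
        check_peptide(self.epitope, context="epitope")
        check_peptide(self.hamming_reference, context="hamming_reference")
        if len(self.hamming_reference) != len(self.epitope):
            raise ValidationError(
                "hamming_reference and epitope must have equal length")
        k = len(self.epitope)
        if not set(self.anchors) <= set(range(1, k + 1)):
            raise ValidationError(f"anchors {self.anchors} out of range 1..{k}")
        if not (self.ic50_max_nm > 0):
            raise ValidationError("ic50_max_nm must be positive")
        if not (0 < self.activation_threshold < 1):
            raise ValidationError("activation_threshold must be in (0, 1)")
        if self.scenario is None:
            for name in ("measurements", "proteome", "affinity"):
                path = getattr(self, name)
                if path is None:
                    raise ValidationError(f"missing required input path: {name}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")
        elif self.scenario not in ("default", "small"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")

    def resolved(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["anchors"] = list(self.anchors)
        d["bin_edges"] = list(self.bin_edges)
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def scenario_from_config(config: RunConfig) -> SyntheticScenario:
    kwargs: dict[str, Any] = dict(
        seed=config.seed,
        epitope=config.epitope,
        anchors=frozenset(config.anchors),
    )
    if config.scenario == "small":
        kwargs.update(n_proteins=300)
    return SyntheticScenario(**kwargs)


@dataclass
class PipelineResult:
    """Everything a caller needs to inspect a finished run."""

    config: RunConfig
    pwm_paths: dict[str, Path]
    hits_path: Path
    motif_paths: list[Path]
    classifier_path: Path | None
    classifier: ClassifierResult | None
    calls: dict[str, bool] | None
    ranked: list = field(repr=False, default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    truth: dict | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in fixed order; deterministic given config."""
    try:
        config.validate()
    except Exception as exc:
        raise StageError("config", exc) from exc

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    anchors = frozenset(config.anchors)
    truth = None

    # --- inputs -----------------------------------------------------------
    @_stage("inputs")
    def load():
        nonlocal truth
        if config.scenario is not None:
            dataset = make_scenario_dataset(scenario_from_config(config))
            truth = {
                "planted": dataset.planted,
                "locations": dataset.truth,
                "scenario": dataset.scenario,
            }
            return (dataset.measurements, dataset.proteins, dataset.affinity,
                    dataset.expression)
        measurements = scan_io.read_measurements(config.measurements)
        proteins = scan_io.read_fasta(config.proteome)
        affinity = scan_io.read_affinity_table(config.affinity)
        expression = (scan_io.read_expression_table(config.expression)
                      if config.expression else None)
        return measurements, proteins, affinity, expression

    measurements, proteins, affinity, expression = load()

    # --- fingerprint ------------------------------------------------------
    @_stage("fingerprint")
    def fingerprint():
        pwms = {}
        paths = {}
        for assay in Assay:
            pwm = build_pwm(measurements, assay, config.epitope, anchors)
            path = outdir / f"{assay.value}.pwm"
            scan_io.write_pwm(pwm, path, extra_metadata={"tool_version": __version__})
            pwms[assay.value] = pwm
            paths[assay.value] = path
        return pwms, paths

    pwms, pwm_paths = fingerprint()

    # --- scan -------------------------------------------------------------
    @_stage("scan")
    def scan():
        index = enumerate_kmers(proteins, len(config.epitope))
        counts["windows_total"] = index.n_windows_total
        counts["windows_skipped"] = index.n_windows_skipped
        counts["unique_peptides"] = len(index)
        filt = filter_by_affinity(index.peptides.keys(), affinity,
                                  config.ic50_max_nm)
        counts["binders"] = len(filt.kept)
        counts["dropped_above_cutoff"] = filt.n_above_cutoff
        counts["dropped_unpredicted"] = filt.n_unpredicted
        return index, filt

    index, filt = scan()

    # --- rank -------------------------------------------------------------
    @_stage("rank")
    def rank():
        return rank_peptides(
            filt.kept, pwms,
            provenance=index.peptides,
            affinity=affinity,
            hamming_reference=config.hamming_reference,
        )

    ranked = rank()
    counts["ranked"] = len(ranked)

    # --- motif ------------------------------------------------------------
    @_stage("motif")
    def motif():
        motifs = bin_and_motif(ranked, config.bin_edges)
        paths = []
        for i, m in enumerate(motifs, start=1):
            path = outdir / f"motif_bin{i}.tsv"
            scan_io.write_motif_matrix(m, path)
            paths.append(path)
        return paths

    motif_paths = motif()

    # --- expression -------------------------------------------------------
    @_stage("expression")
    def expr():
        if expression is None:
            return None
        return annotate_expression(ranked, expression, config.tpm_threshold)

    annotations = expr()

    # --- report -----------------------------------------------------------
    @_stage("report")
    def report():
        path = outdir / "hits.tsv"
        metadata = {"tool_version": __version__,
                    "config": json.dumps(config.resolved(), sort_keys=True)}
        scan_io.write_hits_report(ranked, path, annotations=annotations,
                                  metadata=metadata)
        return path

    hits_path = report()

    # --- classify ---------------------------------------------------------
    @_stage("classify")
    def classify_stage():
        if config.scenario is not None:
            scenario = truth["scenario"]
            items = simulate_outcomes(ranked, scenario.true_cutoff,
                                      scenario.flip_rate, config.seed)
        elif config.labels is not None:
            table = scan_io._read_table(Path(config.labels),
                                        ("peptide", "activation_observed"))
            observed = {
                row.peptide: float(row.activation_observed)
                for row in table.itertuples(index=False)
            }
            by_seq = {sp.sequence: sp.scores.combined for sp in ranked}
            items = [
                LabelledScore.from_activation(
                    pep, by_seq[pep], act, config.activation_threshold)
                for pep, act in observed.items() if pep in by_seq
            ]
        else:
            return None, None, None
        result = select_cutoff(roc_curve(items))
        calls = classify({it.peptide: it.score for it in items}, result.cutoff)
        path = outdir / "classifier.json"
        payload = {
            "auc": result.auc,
            "cutoff": result.cutoff,
            "sensitivity": result.sensitivity,
            "specificity": result.specificity,
            "accuracy": result.accuracy,
            "n_positive": result.n_positive,
            "n_negative": result.n_negative,
            "roc_points": [list(p) for p in result.roc_points],
            "tool_version": __version__,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return result, calls, path

    classifier_result, calls, classifier_path = classify_stage()

    logger.info("pipeline complete: %s", counts)
    return PipelineResult(
        config=config,
        pwm_paths=pwm_paths,
        hits_path=hits_path,
        motif_paths=motif_paths,
        classifier_path=classifier_path,
        classifier=classifier_result,
        calls=calls,
        ranked=ranked,
        counts=counts,
        truth=truth,
    )
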