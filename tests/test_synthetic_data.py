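"""Synthetic-data generators: determinism, noiseless round-trip, planted
structure, anchor-rule affinities and labelled outcomes."""

import numpy as np
import pytest

from tcrfingerprint import (
    SyntheticScenario,
    ValidationError,
    build_pwm,
    enumerate_kmers,
    filter_by_affinity,
    make_kernel,
    pwm_similarity,
    roc_curve,
    score_peptide,
    select_cutoff,
    simulate_affinity,
    simulate_clamp_measurements,
    simulate_measurements,
    simulate_outcomes,
    simulate_proteome,
)
from tcrfingerprint.scoring import ScoredPeptide
from tcrfingerprint.fingerprint import combine_scores
from tcrfingerprint.synthetic_data import plant_peptides, simulate_expression

from conftest import ANCHORS, EPITOPE, random_peptide


class TestMakeKernel:
    def test_same_seed_identical(self):
        a = make_kernel(7, EPITOPE, ANCHORS, {5, 8})
        b = make_kernel(7, EPITOPE, ANCHORS, {5, 8})
        assert np.array_equal(a.weights, b.weights)

    def test_different_seed_differs(self):
        a = make_kernel(7, EPITOPE, ANCHORS, {5, 8})
        b = make_kernel(8, EPITOPE, ANCHORS, {5, 8})
        assert not np.array_equal(a.weights, b.weights)

    def test_double_critical_deviation_score_bound(self, kernel, rng):
        # any peptide differing from the epitope at both P5 and P8 is capped
        bound = (5 * 100 + 2 * 10) / 700.0
        for _ in range(50):
            pep = list(EPITOPE)
            pep[4] = rng.choice([a for a in "ACDEFGHIK" if a != EPITOPE[4]])
            pep[7] = rng.choice([a for a in "LMNPRSTVY" if a != EPITOPE[7]])
            assert score_peptide(kernel, "".join(pep)) <= bound + 1e-12

    def test_no_critical_positions_respects_floor(self):
        k = make_kernel(7, EPITOPE, ANCHORS, set())
        assert k.weights.min() >= 10.0

    def test_critical_outside_scored_rejected(self):
        with pytest.raises(ValidationError):
            make_kernel(7, EPITOPE, ANCHORS, {2})


class TestSimulateMeasurements:
    def test_noiseless_roundtrip_recovers_kernel_exactly(self, kernel):
        scenario = SyntheticScenario(noise_cv=0.0, replicates=1)
        ms = simulate_measurements(kernel, scenario)
        for assay in ("binding", "activation", "killing"):
            recovered = build_pwm(ms, assay, EPITOPE, ANCHORS)
            assert np.allclose(recovered.weights, kernel.weights, atol=1e-9)

    def test_noisy_recovery_high_similarity(self, kernel, default_scenario):
        ms = simulate_measurements(kernel, default_scenario)
        for assay in ("binding", "activation", "killing"):
            recovered = build_pwm(ms, assay, EPITOPE, ANCHORS)
            assert pwm_similarity(recovered, kernel) >= 0.95

    def test_inter_assay_concordance(self, kernel, default_scenario):
        ms = simulate_measurements(kernel, default_scenario)
        pwms = [build_pwm(ms, a, EPITOPE, ANCHORS)
                for a in ("binding", "activation", "killing")]
        for i in range(3):
            for j in range(i + 1, 3):
                assert pwm_similarity(pwms[i], pwms[j]) >= 0.9

    def test_deterministic_per_seed(self, kernel, default_scenario):
        a = simulate_measurements(kernel, default_scenario)
        b = simulate_measurements(kernel, default_scenario)
        assert [(r.peptide, r.signal, r.background) for r in a] == \
               [(r.peptide, r.signal, r.background) for r in b]

    def test_library_coverage(self, kernel, default_scenario):
        ms = simulate_measurements(kernel, default_scenario)
        assert len(ms.peptides("binding")) == 134
        assert len(ms.replicates(EPITOPE, "binding")) == 3


class TestClampMeasurements:
    def test_overdrive_variants_exceed_epitope_mean(self):
        ms, overdrive, negative = simulate_clamp_measurements(seed=20191022)
        epi_mean = np.mean([r.corrected for r in ms.replicates(EPITOPE, "binding")])
        for pep in overdrive:
            mean = np.mean([r.corrected for r in ms.replicates(pep, "binding")])
            assert mean > epi_mean
        for pep in negative:
            mean = np.mean([r.corrected for r in ms.replicates(pep, "binding")])
            assert mean < 0


class TestSimulateProteome:
    def test_pure_decoy_when_no_planted(self):
        scenario = SyntheticScenario(n_proteins=20, protein_length=50)
        proteins, truth = simulate_proteome(scenario, [])
        assert len(proteins) == 20
        assert list(truth) == [EPITOPE]  # the scanning epitope is always embedded

    def test_planted_found_with_recorded_provenance(self):
        scenario = SyntheticScenario(n_proteins=50, protein_length=60)
        planted = ["SLAMWITQV"]
        proteins, truth = simulate_proteome(scenario, planted)
        idx = enumerate_kmers(proteins, 9)
        for pep, locations in truth.items():
            assert pep in idx.peptides
            found = {(p.protein_id, p.start) for p in idx.peptides[pep]}
            assert set(locations) <= found

    def test_planted_pass_synthetic_affinity_filter(self, kernel):
        scenario = SyntheticScenario(n_proteins=100, protein_length=60)
        planted = [p for p, _ in plant_peptides(kernel, scenario)]
        amap = simulate_affinity(planted + [EPITOPE], scenario.anchor_rule,
                                 scenario.seed)
        res = filter_by_affinity(planted + [EPITOPE], amap, 500.0)
        assert res.kept == set(planted) | {EPITOPE}

    def test_planted_longer_than_protein_rejected(self):
        scenario = SyntheticScenario(protein_length=5)
        with pytest.raises(ValidationError):
            simulate_proteome(scenario, [])


class TestPlantPeptides:
    def test_planted_keep_critical_residues_and_score_high(self, kernel,
                                                           default_scenario):
        planted = plant_peptides(kernel, default_scenario)
        assert len(planted) == default_scenario.n_planted
        assert len({p for p, _ in planted}) == default_scenario.n_planted
        for pep, intended in planted:
            assert pep != EPITOPE
            assert pep[4] == EPITOPE[4] and pep[7] == EPITOPE[7]
            assert intended == pytest.approx(score_peptide(kernel, pep))
            assert intended > default_scenario.true_cutoff


class TestSimulateAffinity:
    def test_rule_matching_epitope_is_binder(self, default_scenario):
        amap = simulate_affinity([EPITOPE], default_scenario.anchor_rule, 1)
        assert amap.get(EPITOPE) <= 500.0

    def test_rule_violating_anchor_is_nonbinder(self, default_scenario):
        pep = EPITOPE[0] + "G" + EPITOPE[2:]
        amap = simulate_affinity([pep], default_scenario.anchor_rule, 1)
        assert amap.get(pep) > 500.0

    def test_decoy_pass_rate_matches_rule_probability(self, rng,
                                                      default_scenario):
        n = 20000
        decoys = list({random_peptide(rng) for _ in range(n)})
        amap = simulate_affinity(decoys, default_scenario.anchor_rule, 1)
        passed = sum(1 for p in decoys if amap.get(p) <= 500.0)
        p_match = (2 / 20) * (3 / 20)
        se = np.sqrt(p_match * (1 - p_match) / len(decoys))
        assert abs(passed / len(decoys) - p_match) <= 3 * se

    def test_order_independent(self, rng, default_scenario):
        peps = [random_peptide(rng) for _ in range(100)]
        a = simulate_affinity(peps, default_scenario.anchor_rule, 5)
        b = simulate_affinity(peps[::-1], default_scenario.anchor_rule, 5)
        assert dict(a.items()) == dict(b.items())


class TestSimulateOutcomes:
    def scored_set(self, rng, n=60):
        out = []
        for i in range(n):
            s = float(rng.uniform(0.2, 1.0))
            out.append(ScoredPeptide(sequence=random_peptide(rng),
                                     scores=combine_scores(s, s, s)))
        return out

    def test_clean_labels_give_perfect_classifier(self, rng):
        scored = self.scored_set(rng)
        items = simulate_outcomes(scored, true_cutoff=0.8, flip_rate=0.0, seed=3)
        res = select_cutoff(roc_curve(items))
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_noisy_labels_recover_cutoff_in_gap(self, rng):
        # two well-separated score clusters with 10% label noise
        scored = []
        for i in range(100):
            s = float(np.linspace(0.90, 1.0, 100)[i])
            scored.append(ScoredPeptide(sequence=random_peptide(rng),
                                        scores=combine_scores(s, s, s)))
        for i in range(100):
            s = float(np.linspace(0.2, 0.6, 100)[i])
            scored.append(ScoredPeptide(sequence=random_peptide(rng),
                                        scores=combine_scores(s, s, s)))
        items = simulate_outcomes(scored, true_cutoff=0.75, flip_rate=0.1, seed=3)
        res = select_cutoff(roc_curve(items))
        # max-sensitivity drags the cutoff to the lowest labelled positive,
        # which with flipped low-cluster labels sits in the low cluster
        assert res.cutoff <= 0.90
        assert res.sensitivity == 1.0

    def test_deterministic(self, rng):
        scored = self.scored_set(rng)
        a = simulate_outcomes(scored, 0.8, 0.2, seed=9)
        b = simulate_outcomes(scored, 0.8, 0.2, seed=9)
        assert a == b

    def test_bad_flip_rate_rejected(self, rng):
        with pytest.raises(ValidationError):
            simulate_outcomes(self.scored_set(rng), 0.8, 0.6, seed=1)


def test_expression_profiles_deterministic_and_nonnegative():
    genes = [f"G{i}" for i in range(50)]
    a = simulate_expression(genes, seed=2)
    b = simulate_expression(genes, seed=2)
    assert a.table.equals(b.table)
    assert (a.table.values >= 0).all()
    assert len(a.tissues) == 37
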