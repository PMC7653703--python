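"""Generator behavior: probe maps, cohort truth, forward L2R model."""

import math

import numpy as np
import pandas as pd
import pytest

from cnvprog.genome import InvalidConfigError, generate_probe_map, hg19_autosomes
from cnvprog.prognosis import build_design, fit_logistic
from cnvprog.synthetic_data import (
    CohortConfig,
    TypeParams,
    TruthSet,
    _default_type_params,
    generate_cohort_truth,
    simulate_expression,
    simulate_homozygosity,
    simulate_l2r_profiles,
    make_gene_annotation,
)


def _lactotroph_only(n: int) -> CohortConfig:
    tp = {
        k: TypeParams(**{**v.__dict__, "n": n if k == "lactotroph" else 0})
        for k, v in _default_type_params().items()
    }
    return CohortConfig(type_params=tp)


class TestProbeMap:
    def test_probe_count_and_allocation(self, genome):
        pm = generate_probe_map(genome, 99_659, snp_fraction=0.0, seed=0)
        assert len(pm) == 99_659
        assert (pm.table["probe_class"] == "CGH").all()
        # allocation proportional to chromosome length within rounding
        counts = pm.table.groupby("chrom").size()
        share1 = genome.lengths[1] / genome.total_length
        assert counts[1] == pytest.approx(99_659 * share1, rel=0.01)

    def test_one_probe_per_chromosome_at_minimum(self, genome):
        pm = generate_probe_map(genome, 22, snp_fraction=0.0, seed=0)
        assert pm.table.groupby("chrom").size().eq(1).all()

    def test_deterministic_under_seed(self, genome):
        a = generate_probe_map(genome, 500, snp_fraction=0.3, seed=9)
        b = generate_probe_map(genome, 500, snp_fraction=0.3, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_too_few_probes_rejected(self, genome):
        with pytest.raises(InvalidConfigError):
            generate_probe_map(genome, 10, seed=0)

    def test_snp_fraction(self, genome):
        pm = generate_probe_map(genome, 4000, snp_fraction=0.25, seed=0)
        assert pm.is_snp.sum() == 1000


class TestCohortTruth:
    def test_default_cohort_composition(self, probe_map):
        truth = generate_cohort_truth(CohortConfig(), probe_map, seed=0)
        sizes = truth.clinical_table().groupby("tumor_type").size()
        assert sizes.to_dict() == {
            "gonadotroph": 56, "immunonegative": 11, "somatotroph": 56,
            "lactotroph": 39, "corticotroph": 33,
        }

    def test_events_within_genome_and_states_valid(self, probe_map):
        genome = hg19_autosomes()
        truth = generate_cohort_truth(CohortConfig(), probe_map, seed=3)
        for s in truth.samples:
            assert s.recurrence in (0, 1)
            for ev in s.events:
                assert ev.state in ("gain", "loss")
                assert 1 <= ev.start <= ev.end <= genome.lengths[ev.chrom]

    def test_gains_outnumber_losses(self, probe_map):
        truth = generate_cohort_truth(CohortConfig(), probe_map, seed=4)
        tm = truth.truth_matrix(probe_map).to_numpy()
        assert (tm == 1).sum() > (tm == -1).sum()

    def test_burden_median_calibration(self, dense_probe_map):
        """Over 500 lactotroph tumors the median altered fraction sits within
        5 percentage points of the configured 38.3% target."""
        truth = generate_cohort_truth(_lactotroph_only(500), dense_probe_map, seed=7)
        med = np.median([s.altered_fraction for s in truth.samples])
        assert abs(med - 0.383) < 0.05

    def test_null_burden_effect_gives_flat_slope(self, dense_probe_map):
        cfg = _lactotroph_only(500)
        cfg = CohortConfig(type_params=cfg.type_params, or_burden_lactotroph=1.0)
        truth = generate_cohort_truth(cfg, dense_probe_map, seed=13)
        clin = truth.clinical_table()
        x = np.log2(np.array([s.altered_fraction for s in truth.samples])
                    * len(dense_probe_map) + 1)
        fit = fit_logistic(clin["recurrence"].to_numpy(float),
                           np.column_stack([np.ones(len(x)), x]),
                           columns=["intercept", "burden"])
        assert abs(fit.coef[1]) < 0.1

    def test_planted_or_recovered_at_large_n(self, dense_probe_map):
        truth = generate_cohort_truth(_lactotroph_only(2000), dense_probe_map, seed=11)
        clin = truth.clinical_table()
        x = np.log2(np.array([s.altered_fraction for s in truth.samples])
                    * len(dense_probe_map) + 1)
        X0, names = build_design(clin, ["grade", "age", "sex"])
        fit = fit_logistic(clin["recurrence"].to_numpy(float),
                           np.column_stack([X0, x]), columns=names + ["burden"])
        assert 1.2 <= fit.odds_ratio("burden") <= 1.4

    def test_burden_target_above_one_rejected(self):
        with pytest.raises(InvalidConfigError):
            TypeParams(10, 0.5, 1.2, 1.5, 0.1, 1.0, 0.5, 0.5, 0.1)

    def test_determinism_and_roundtrip(self, probe_map):
        a = generate_cohort_truth(CohortConfig(), probe_map, seed=5)
        b = generate_cohort_truth(CohortConfig(), probe_map, seed=5)
        assert a.to_dict() == b.to_dict()
        assert TruthSet.from_dict(a.to_dict()).to_dict() == a.to_dict()


class TestL2RForwardModel:
    def test_no_events_no_noise_gives_zero_matrix(self, probe_map):
        truth = TruthSet(samples=[], n_probes=len(probe_map))
        cfg = CohortConfig(type_params={
            k: TypeParams(**{**v.__dict__, "n": 0, "p_altered": 0.0})
            for k, v in _default_type_params().items()})
        # build a tiny cohort with no alterations
        tp = {k: TypeParams(**{**v.__dict__,
                               "n": 3 if k == "gonadotroph" else 0,
                               "p_altered": 0.0})
              for k, v in _default_type_params().items()}
        truth = generate_cohort_truth(CohortConfig(type_params=tp), probe_map, seed=1)
        l2r = simulate_l2r_profiles(truth, probe_map, noise_sd=0.0, seed=0)
        assert (l2r.to_numpy() == 0).all()

    def test_gain_dosage_closed_form(self, probe_map):
        truth = generate_cohort_truth(_lactotroph_only(5), probe_map, seed=2)
        l2r = simulate_l2r_profiles(truth, probe_map, noise_sd=0.0, purity=1.0, seed=0)
        tm = truth.truth_matrix(probe_map)
        gained = l2r.to_numpy().T[tm.to_numpy() == 1]
        lost = l2r.to_numpy().T[tm.to_numpy() == -1]
        assert np.allclose(gained, math.log2(1.5))
        assert np.allclose(lost, -1.0)

    def test_noise_sd_matches_target(self, dense_probe_map):
        truth = generate_cohort_truth(_lactotroph_only(1), dense_probe_map, seed=2)
        clean = simulate_l2r_profiles(truth, dense_probe_map, noise_sd=0.0, seed=0)
        noisy = simulate_l2r_profiles(truth, dense_probe_map, noise_sd=0.15, seed=0)
        resid = (noisy - clean).to_numpy().ravel()
        assert np.std(resid) == pytest.approx(0.15, rel=0.05)

    def test_cnloh_does_not_move_l2r_but_sets_homozygosity(self, dense_probe_map):
        truth = generate_cohort_truth(_lactotroph_only(30), dense_probe_map, seed=6)
        sample = next(s for s in truth.samples if s.loh_events)
        j = truth.sample_ids.index(sample.sample_id)
        l2r = simulate_l2r_profiles(truth, dense_probe_map, noise_sd=0.0, seed=0)
        tm = truth.truth_matrix(dense_probe_map).to_numpy()
        ev = sample.loh_events[0]
        sel = slice(ev.probe_start, ev.probe_end + 1)
        assert np.allclose(
            l2r.iloc[sel, j][tm[j, sel] == 0], 0.0)  # copy neutral: no L2R shift
        hom = simulate_homozygosity(truth, dense_probe_map, seed=0)
        snp_idx = np.flatnonzero(dense_probe_map.is_snp)
        in_loh = (snp_idx >= ev.probe_start) & (snp_idx <= ev.probe_end)
        assert hom.iloc[in_loh, j].all()


class TestExpressionForwardModel:
    def test_null_fold_change_near_one(self, probe_map):
        tp = {k: TypeParams(**{**v.__dict__,
                               "n": 32 if k == "lactotroph" else 0, "p_altered": 0.0})
              for k, v in _default_type_params().items()}
        truth = generate_cohort_truth(CohortConfig(type_params=tp), probe_map, seed=3)
        genes = make_gene_annotation(n_genes=50, seed=0)
        expr = simulate_expression(truth, genes, seed=0, noise_log2_sd=0.1)
        clin = truth.clinical_table()
        rec = expr.loc[:, clin["recurrence"] == 1].mean(axis=1)
        non = expr.loc[:, clin["recurrence"] == 0].mean(axis=1)
        assert ((rec / non).between(0.8, 1.25)).mean() > 0.9

    def test_planted_recurrence_effect_recovered(self, probe_map):
        tp = {k: TypeParams(**{**v.__dict__,
                               "n": 32 if k == "lactotroph" else 0, "p_altered": 0.0})
              for k, v in _default_type_params().items()}
        truth = generate_cohort_truth(CohortConfig(type_params=tp), probe_map, seed=8)
        genes = make_gene_annotation(n_genes=100, seed=0)
        target = genes["gene"].iloc[0]
        expr = simulate_expression(truth, genes, de_genes={target: 2.0},
                                   seed=1, noise_log2_sd=0.05)
        clin = truth.clinical_table()
        fc = (expr.loc[target, clin["recurrence"] == 1].mean()
              / expr.loc[target, clin["recurrence"] == 0].mean())
        assert 1.8 <= fc <= 2.2

    def test_unknown_de_gene_rejected(self, probe_map):
        truth = generate_cohort_truth(_lactotroph_only(4), probe_map, seed=1)
        genes = make_gene_annotation(n_genes=10, seed=0)
        with pytest.raises(KeyError):
            simulate_expression(truth, genes, de_genes={"NOT_A_GENE": 2.0}, seed=0)
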