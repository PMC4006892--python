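"""Synthetic-data generator: determinism, spike fidelity, truth completeness."""

import numpy as np
import pytest

from mhgpipe.errors import ConfigError
from mhgpipe.preprocess import detect_probes
from mhgpipe.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_gene_sets,
    simulate_qpcr,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_per_group": 1}, "n_per_group"),
            ({"de_fold_changes": (1.5, -2.0)}, "de_fold_changes"),
            ({"set_size_range": (10, 600), "n_genes": 500}, "set_size_range"),
            ({"n_probes": 100, "n_genes": 500}, "n_probes"),
            ({"de_fraction": 1.5}, "de_fraction"),
        ],
    )
    def test_invalid_config_names_the_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimulationConfig(**kwargs)


class TestSimulateExpression:
    def test_identical_seed_gives_byte_identical_output(self):
        cfg = SimulationConfig(seed=1, n_genes=100)
        m1, t1 = simulate_expression(cfg)
        m2, t2 = simulate_expression(cfg)
        assert m1.values.to_csv() == m2.values.to_csv()
        assert t1.probe_fold.to_csv() == t2.probe_fold.to_csv()

    def test_different_seeds_differ(self):
        a, _ = simulate_expression(SimulationConfig(seed=1, n_genes=100))
        b, _ = simulate_expression(SimulationConfig(seed=2, n_genes=100))
        assert not a.values.equals(b.values)

    def test_null_simulation_has_unit_folds(self):
        _, truth = simulate_expression(SimulationConfig(seed=3, de_fraction=0.0))
        assert (truth.probe_fold == 1.0).all()
        assert not truth.probe_de.any() and not truth.gene_de.any()

    def test_shape_and_group_labels(self):
        cfg = SimulationConfig(seed=4, n_genes=200, n_probes=300, n_per_group=4)
        m, _ = simulate_expression(cfg)
        assert m.n_probes == 300 and m.n_samples == 8
        assert m.group_names() == ["scramble", "sirna"]
        assert (m.groups.value_counts() == 4).all()

    def test_realized_spike_matches_noise_model(self):
        # DE probes' mean log2 group difference should match log2(2)=1 within
        # 3 standard errors of the noise model: sd = noise_sd*sqrt(2/n),
        # averaged over n_DE probes
        cfg = SimulationConfig(
            seed=5, n_genes=1000, n_probes=1000, n_per_group=4,
            noise_sd=0.3, de_fraction=0.1, de_fold_changes=(2.0,),
            de_down_fraction=0.0,
        )
        m, truth = simulate_expression(cfg)
        de = truth.probe_de.to_numpy()
        diff = (m.group_values("sirna").mean(axis=1) - m.group_values("scramble").mean(axis=1))
        n_de = de.sum()
        tol = 3 * (0.3 * np.sqrt(2 / 4)) / np.sqrt(n_de)
        assert abs(diff[de].mean() - 1.0) <= tol

    def test_undetected_probes_sit_below_the_floor(self):
        cfg = SimulationConfig(seed=6, n_genes=300, undetected_fraction=0.1,
                               detection_floor=5.0)
        m, truth = simulate_expression(cfg)
        below = (m.values.max(axis=1) <= 5.0)
        expected = round(0.1 * m.n_probes)
        assert below.sum() >= expected  # the shifted block, at least
        res = detect_probes(m, 5.0)
        assert (~res.detected_mask).sum() >= expected

    def test_truth_covers_every_probe_and_gene(self):
        m, truth = simulate_expression(SimulationConfig(seed=7, n_genes=150))
        assert list(truth.probe_fold.index) == list(m.values.index)
        assert truth.gene_de.index.equals(truth.gene_fold.index)
        assert set(m.genes) <= set(truth.gene_de.index)


class TestSimulateGeneSets:
    def test_forced_size(self):
        cfg = SimulationConfig(seed=8, n_genes=100, n_gene_sets=10,
                               set_size_range=(5, 5))
        _, truth = simulate_expression(cfg)
        sets, truth = simulate_gene_sets(cfg, truth)
        assert len(sets) == 10
        assert all(len(s.members) == 5 for s in sets)

    def test_no_enriched_ids_means_all_null(self):
        cfg = SimulationConfig(seed=9, n_genes=100)
        _, truth = simulate_expression(cfg)
        sets, truth = simulate_gene_sets(cfg, truth)
        assert len(truth.set_enriched) == len(sets)
        assert not truth.set_enriched.any()

    def test_enriched_sets_concentrate_de_genes(self):
        cfg = SimulationConfig(seed=10, n_genes=200, de_fraction=0.2,
                               enriched_set_ids=("SET001",))
        _, truth = simulate_expression(cfg)
        sets, truth = simulate_gene_sets(cfg, truth)
        spiked = next(s for s in sets if s.name == "SET001")
        de_frac = np.mean([truth.gene_de[g] for g in spiked.members])
        assert de_frac >= 0.7  # 80% by construction, minus rounding
        assert truth.set_enriched["SET001"]

    def test_unknown_enriched_id_rejected(self):
        cfg = SimulationConfig(seed=11, n_genes=100, enriched_set_ids=("NOPE",))
        _, truth = simulate_expression(cfg)
        with pytest.raises(ConfigError, match="NOPE"):
            simulate_gene_sets(cfg, truth)


class TestSimulateQpcr:
    def test_noise_free_table_is_exact(self):
        table, _ = simulate_qpcr(["T"], 1.0, n=3, ct_sd=0.0, seed=12)
        ref = table[table.target == "GAPDH"].set_index("sample_id")["ct"]
        tgt = table[table.target == "T"].set_index("sample_id")["ct"]
        dct = tgt - ref.loc[tgt.index]
        assert dct.nunique() == 1  # true_rq=1, no noise: ddCt identically 0

    def test_reference_ct_independent_of_group(self):
        table, _ = simulate_qpcr(["T"], 2.0, n=5, ct_sd=0.0, seed=13)
        ref = table[table.target == "GAPDH"]
        assert ref.groupby("group")["ct"].nunique().eq(1).all()

    def test_monte_carlo_recovery_calibrated_to_noise_model(self):
        # true_rq=2, ct_sd=0.2 per well, n=6 per group. dCt carries noise from
        # two wells (sd 0.2*sqrt(2)) and log2(RQ_hat) has
        # sd = 0.2*sqrt(2)*sqrt(2/6) ~= 0.163; across 100 seeds the recovered
        # log2 RQs must be unbiased (3 SE of the grand mean) and every value
        # within 4.5 sd of the truth
        from mhgpipe.qpcr import relative_quantity

        sd = 0.2 * np.sqrt(2.0) * np.sqrt(2.0 / 6.0)
        log2_rqs = []
        for seed in range(100):
            table, _ = simulate_qpcr(["T"], 2.0, n=6, ct_sd=0.2, seed=seed)
            log2_rqs.append(np.log2(relative_quantity(table, "T").rq))
        log2_rqs = np.array(log2_rqs)
        assert abs(log2_rqs.mean() - 1.0) <= 3 * sd / 10
        assert np.abs(log2_rqs - 1.0).max() <= 4.5 * sd
        assert 0.5 * sd <= log2_rqs.std(ddof=1) <= 2.0 * sd

    @pytest.mark.parametrize("bad_rq", [0.0, -0.5])
    def test_non_positive_rq_rejected(self, bad_rq):
        with pytest.raises(ConfigError, match="true_rq"):
            simulate_qpcr(["T"], bad_rq, n=3, ct_sd=0.1, seed=0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigError, match="n >= 2"):
            simulate_qpcr(["T"], 1.0, n=1, ct_sd=0.1, seed=0)
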