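"""The generator's latent truth, spot tables and networks match their
documented construction and random-stream discipline."""

import numpy as np
import pandas as pd
import pytest

import costim_synergy as cs
from costim_synergy.simdata import CLASS_ADDITIVE, CLASS_NULL, CLASS_SUPRA


class TestSimulateTruth:
    def test_no_effect_config_gives_flat_truth(self):
        cfg = cs.SimConfig(n_genes=200, frac_regulated_a=0,
                           frac_regulated_b=0, frac_supra=0, seed=1)
        truth = cs.simulate_truth(cfg)
        assert (truth.synergy_class == CLASS_NULL).all()
        for fc in (truth.fc_a, truth.fc_b, truth.fc_combo):
            assert np.all(fc == 1.0)

    def test_supra_count_matches_independent_redraw(self):
        """The supra class comes from the first uniform draw of the truth
        substream; an independent redraw must give the same count."""
        cfg = cs.SimConfig(n_genes=10_000, frac_supra=0.02, seed=77)
        truth = cs.simulate_truth(cfg)
        rng = cs.substream(77, 0)
        expected = int((rng.random(10_000) < 0.02).sum())
        assert (truth.synergy_class == CLASS_SUPRA).sum() == expected

    def test_class_invariants(self):
        cfg = cs.SimConfig(n_genes=5000, seed=3)
        truth = cs.simulate_truth(cfg)
        supra = truth.synergy_class == CLASS_SUPRA
        add = truth.synergy_class == CLASS_ADDITIVE
        null = truth.synergy_class == CLASS_NULL
        assert np.all(truth.fc_combo[supra]
                      >= 1.5 * (truth.fc_a[supra] + truth.fc_b[supra]) - 1e-12)
        np.testing.assert_allclose(
            truth.fc_combo[add], truth.fc_a[add] + truth.fc_b[add] - 1.0)
        assert np.all(truth.fc_a[null] == 1.0)
        assert np.all(truth.fc_combo[null] == 1.0)
        assert np.all(truth.fc_a > 0) and np.all(truth.fc_combo > 0)

    def test_log_additive_combination_rule(self):
        cfg = cs.SimConfig(n_genes=2000, combine="log_additive", seed=3)
        truth = cs.simulate_truth(cfg)
        add = truth.synergy_class == CLASS_ADDITIVE
        np.testing.assert_allclose(
            truth.fc_combo[add], truth.fc_a[add] * truth.fc_b[add])

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValueError, match="sum above 1"):
            cs.SimConfig(frac_regulated_a=0.5, frac_regulated_b=0.4,
                         frac_supra=0.2)

    @pytest.mark.parametrize("field,value", [
        ("n_replicates", 1), ("noise_sd", -0.1), ("flag_rate", 1.5),
        ("supra_min", 1.2), ("combine", "multiplicative"),
    ])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            cs.SimConfig(**{field: value})


class TestSimulateArrays:
    def test_determinism_and_conservation(self, small_config, small_experiment):
        truth, tables, design = small_experiment
        truth2 = cs.simulate_truth(small_config)
        tables2, design2 = cs.simulate_arrays(truth2, small_config)
        assert len(tables) == 4 * small_config.n_replicates
        pd.testing.assert_frame_equal(design, design2)
        for t1, t2 in zip(tables, tables2):
            pd.testing.assert_frame_equal(t1.data, t2.data)
            # every gene appears exactly once per array
            assert list(t1.data["gene_id"]) == truth.gene_ids

    def test_noise_free_null_arrays_have_zero_ratio(self):
        cfg = cs.SimConfig(n_genes=300, frac_regulated_a=0, frac_regulated_b=0,
                           frac_supra=0, noise_sd=0, dye_bias_amplitude=0,
                           flag_rate=0, low_intensity_rate=0, seed=5)
        truth = cs.simulate_truth(cfg)
        tables, _ = cs.simulate_arrays(truth, cfg)
        for spots in tables:
            np.testing.assert_allclose(spots.data["ch_sample"],
                                       spots.data["ch_reference"])

    def test_planted_gene_mean_ratio_matches_sampling_distribution(self):
        """A gene with combination fold change 8 must show mean log2 ratio
        within 3 standard errors of 3.0 across the combo replicates."""
        n, noise = 200, 0.1
        cfg = cs.SimConfig(n_genes=n, noise_sd=noise, dye_bias_amplitude=0,
                           flag_rate=0, low_intensity_rate=0,
                           background_level=0, n_replicates=3, seed=11)
        gene_ids = cs.simulate_truth(cfg).gene_ids
        fc = np.ones(n)
        fc[0] = 8.0
        truth = cs.SimTruth(gene_ids, np.ones(n), np.ones(n), fc,
                            np.array([CLASS_SUPRA] + [CLASS_NULL] * (n - 1)),
                            seed=cfg.seed)
        tables, design = cs.simulate_arrays(truth, cfg)
        ratios = []
        for spots, (_, row) in zip(tables, design.iterrows()):
            if row["condition"] == "combo":
                d = spots.data.iloc[0]
                ratios.append(np.log2(d["ch_sample"] / d["ch_reference"]))
        assert abs(np.mean(ratios) - 3.0) < 3 * noise / np.sqrt(3)

    def test_flag_count_matches_independent_redraw(self):
        """Flags are the third block of each array substream: jitter (n),
        noise (n), then flag uniforms (n)."""
        cfg = cs.SimConfig(n_genes=1000, flag_rate=0.05, seed=13)
        truth = cs.simulate_truth(cfg)
        tables, _ = cs.simulate_arrays(truth, cfg)
        for i, spots in enumerate(tables):
            rng = cs.substream(13, 1 + i)
            rng.normal(size=1000)  # reference jitter
            rng.normal(size=1000)  # replicate noise
            expected = int((rng.random(1000) < 0.05).sum())
            assert int(spots.data["flag"].sum()) == expected

    def test_null_unflagged_ratios_center_on_zero_after_bias_removal(self):
        cfg = cs.SimConfig(n_genes=4000, frac_regulated_a=0, frac_regulated_b=0,
                           frac_supra=0, noise_sd=0.15, flag_rate=0,
                           low_intensity_rate=0, background_level=0, seed=21)
        truth = cs.simulate_truth(cfg)
        tables, _ = cs.simulate_arrays(truth, cfg)
        spots = tables[0].data
        m = np.log2(spots["ch_sample"] / spots["ch_reference"])
        a = 0.5 * np.log2(spots["ch_sample"] * spots["ch_reference"])
        # subtract the injected bias analytically (A differs from the
        # pre-bias A by bias/2, a second-order effect absorbed below)
        bias = cs.dye_bias_profile(a, cfg.dye_bias_amplitude,
                                   cfg.baseline_log_mean)
        resid = m - bias
        se = resid.std(ddof=1) / np.sqrt(len(resid))
        assert abs(resid.mean()) < 4 * se + 0.02  # small A-shift tolerance


class TestSimulateNetwork:
    def test_planted_major_out_degree_exact(self):
        universe = [f"g{i}" for i in range(100)]
        net = cs.simulate_network(universe, n_major=1, n_minor=0,
                                  coverage_major=0.40, seed=1, sparse_rate=0)
        degrees = [d for _, d in net.graph.out_degree() if d > 0]
        assert degrees == [40]

    def test_major_union_recomputed_by_set_algebra(self):
        universe = [f"g{i}" for i in range(100)]
        net = cs.simulate_network(universe, n_major=4, n_minor=0,
                                  coverage_major=0.40, seed=2, sparse_rate=0)
        majors = [n for n, d in net.graph.out_degree() if d > 0]
        union = set()
        for m in majors:
            union |= set(net.graph.successors(m))
        assert 40 <= len(union) <= 100
        assert len(union) == len({t for _, t in net.edges})

    def test_no_hubs_no_sparse_gives_empty_network(self):
        net = cs.simulate_network([f"g{i}" for i in range(20)], 0, 0,
                                  seed=3, sparse_rate=0)
        assert net.edges == set()

    def test_coverage_precondition_enforced(self):
        universe = [f"g{i}" for i in range(50)]
        with pytest.raises(ValueError):
            cs.simulate_network(universe, 1, 0, coverage_major=0.25, seed=1)
        with pytest.raises(ValueError):
            cs.simulate_network(universe, 1, 1, coverage_minor=0.05, seed=1)
        with pytest.raises(ValueError):
            cs.simulate_network(universe, 1, 0, coverage_major=1.2, seed=1)
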