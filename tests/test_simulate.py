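import numpy as np
import pandas as pd
import pytest

from nestnet.errors import InvalidConfigError
from nestnet.simulate import (
    SimDesign,
    SimModuleSpec,
    generate_behavior,
    generate_categories,
    generate_design,
    generate_expression,
)


def module_spec(n_genes=20, base=1.0, mult=None, coupling=0.0, module_id="m1"):
    return SimModuleSpec(module_id, n_genes, base,
                         mult or {"E": 1.0, "NM": 1.0, "NP": 1.0},
                         trait_coupling=coupling)


class TestDesign:
    def test_full_study_has_300_samples(self):
        meta = generate_design(SimDesign())
        assert len(meta) == 300
        assert meta["sample_id"].is_unique

    def test_small_design_sample_count(self):
        d = SimDesign(n_trials=2, regions=("AMP",), sexes=("M",))
        assert len(generate_design(d)) == 6  # 2 trials x 3 treatments

    def test_same_config_is_byte_identical(self):
        a = generate_design(SimDesign(seed=5)).to_csv()
        b = generate_design(SimDesign(seed=5)).to_csv()
        assert a == b

    def test_treatments_balanced_within_each_stratum(self):
        meta = generate_design(SimDesign(n_trials=7))
        counts = meta.groupby(["region", "sex"])["treatment"].value_counts()
        assert (counts == 7).all()

    def test_empty_region_list_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimDesign(regions=())

    def test_single_trial_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimDesign(n_trials=1)


class TestExpression:
    def test_expected_correlation_closed_form(self):
        d = SimDesign(n_trials=2, regions=("AMP",))
        spec = module_spec(base=1.0, mult={"E": 1.0, "NM": 0.0, "NP": 1.0})
        _, truth = generate_expression(d, [spec], noise_sd=1.0, seed=0)
        assert truth.expected_correlation["m1"]["E"] == pytest.approx(0.5)
        assert truth.expected_correlation["m1"]["NM"] == 0.0

    def test_determinism(self):
        d = SimDesign(n_trials=3, regions=("AMP",))
        a, _ = generate_expression(d, [module_spec()], 10, seed=9)
        b, _ = generate_expression(d, [module_spec()], 10, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_emitted_scale_is_nonnegative_tpm(self):
        d = SimDesign(n_trials=2, regions=("AMP",))
        expr, _ = generate_expression(d, [module_spec()], 5, seed=1, dropout_rate=0.1)
        assert expr.scale == "tpm"
        assert (expr.values >= 0).all()
        assert (expr.values == 0).any()  # dropout injects zeros

    def test_negative_multiplier_rejected(self):
        d = SimDesign(n_trials=2, regions=("AMP",))
        bad = module_spec(mult={"E": -1.0, "NM": 1.0, "NP": 1.0})
        with pytest.raises(InvalidConfigError):
            generate_expression(d, [bad], seed=0)

    def test_missing_multiplier_rejected(self):
        d = SimDesign(n_trials=2, regions=("AMP",))
        bad = module_spec(mult={"E": 1.0, "NM": 1.0})
        with pytest.raises(InvalidConfigError):
            generate_expression(d, [bad], seed=0)

    def test_empirical_correlation_calibrated_at_large_n(self):
        # one stratum, 1000 samples: empirical within-module correlation
        # converges to loading^2/(loading^2 + noise^2) within +-0.02
        d = SimDesign(n_trials=1000 // 3 + 1, regions=("AMP",), sexes=("M",))
        spec = module_spec(n_genes=30, base=1.0)
        expr, truth = generate_expression(d, [spec], seed=12)
        logged = np.log2(expr.values + 1.0)
        C = np.corrcoef(logged[:30])
        mean_r = C[np.triu_indices(30, 1)].mean()
        assert mean_r == pytest.approx(0.5, abs=0.02)

    def test_monte_carlo_differential_correlation(self, rng):
        # 50-gene module, 10 samples per group, target corr_E=0.6 / corr_NP=0.3
        d = SimDesign(n_trials=10, regions=("AMP",), sexes=("M",))
        mult_np = np.sqrt((0.3 / 0.7) / (0.6 / 0.4))
        spec = SimModuleSpec("m1", 50, np.sqrt(0.6 / 0.4),
                             {"E": 1.0, "NM": 1.0, "NP": mult_np})
        r_e, r_np = [], []
        for rep in range(100):
            expr, truth = generate_expression(d, [spec], seed=1000 + rep)
            meta = generate_design(d)
            logged = np.log2(expr.values + 1.0)
            for grp, acc in (("E", r_e), ("NP", r_np)):
                cols = np.flatnonzero((meta["treatment"] == grp).to_numpy())
                C = np.corrcoef(logged[:, cols])
                acc.append(C[np.triu_indices(50, 1)].mean())
        assert truth.expected_correlation["m1"]["E"] == pytest.approx(0.6)
        assert truth.expected_correlation["m1"]["NP"] == pytest.approx(0.3)
        assert np.mean(r_e) == pytest.approx(0.6, abs=0.1)
        assert np.mean(r_np) == pytest.approx(0.3, abs=0.1)


class TestBehavior:
    def setup_sim(self, coupling, seed=0):
        d = SimDesign(n_trials=10, regions=("AMP",), sexes=("M",), seed=seed)
        spec = module_spec(coupling=coupling)
        meta = generate_design(d)
        _, truth = generate_expression(d, [spec], seed=seed)
        return d, meta, truth

    def test_full_coupling_zero_noise_gives_r_one(self):
        _, meta, truth = self.setup_sim(coupling=1.0)
        out = generate_behavior(meta, truth, {"fetch_material_male": "m1"},
                                noise_sd=0.0, seed=1, base=1800.0, scale=100.0)
        e = out[out.treatment == "E"]
        f = truth.factors.loc[e["sample_id"], "m1"]
        r = np.corrcoef(f, e["fetch_material_male"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_zero_coupling_gives_small_null_correlations(self):
        hits = 0
        reps = 300
        for rep in range(reps):
            _, meta, truth = self.setup_sim(coupling=0.0, seed=rep)
            out = generate_behavior(meta, truth, {"fetch_material_male": "m1"},
                                    noise_sd=50.0, seed=rep, base=1800.0)
            e = out[out.treatment == "E"]
            f = truth.factors.loc[e["sample_id"], "m1"]
            r = np.corrcoef(f, e["fetch_material_male"])[0, 1]
            hits += abs(r) < 0.4
        # null |r| < 0.4 at n=10 happens ~76% of the time; require a sane bound
        assert hits / reps > 0.6

    def test_clipping_to_valid_range(self):
        _, meta, truth = self.setup_sim(coupling=1.0)
        out = generate_behavior(meta, truth, {"fetch_material_male": "m1"},
                                noise_sd=0.0, seed=1, base=-5.0, scale=0.0)
        e = out[out.treatment == "E"]
        assert (e["fetch_material_male"] == 0.0).all()  # affine -5 stored as 0
        assert out["fetch_material_male"].between(0, 3600).all()

    def test_nonnesting_frequencies_near_zero(self):
        _, meta, truth = self.setup_sim(coupling=0.5)
        out = generate_behavior(meta, truth, {"stay_nestbox_male": "m1"},
                                seed=2, base=1800.0)
        nn = out[out.treatment != "E"]["stay_nestbox_male"]
        assert nn.abs().max() < 100

    def test_unknown_module_rejected(self):
        _, meta, truth = self.setup_sim(coupling=0.5)
        with pytest.raises(InvalidConfigError):
            generate_behavior(meta, truth, {"fetch_material_male": "nope"}, seed=0)


class TestCategories:
    genes = [f"g{i}" for i in range(200)]

    def test_planted_full_no_background_matches_closed_form(self):
        planted = self.genes[:20]
        cmap = generate_categories(self.genes, {"neuron_projection": 0},
                                   planted_list=planted, planted_fraction=1.0, seed=0)
        assert cmap.genes_in("neuron_projection") == set(planted)

    def test_empty_planted_list_is_valid(self):
        cmap = generate_categories(self.genes, {"other_neurogenesis": 30}, seed=1)
        assert len(cmap.genes_in("other_neurogenesis")) == 30

    def test_planted_not_subset_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_categories(self.genes, {"neuron_projection": 10},
                                planted_list=["alien"], seed=0)

    def test_oversized_category_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_categories(self.genes, {"neuron_projection": 500}, seed=0)

    def test_background_rate_matches_size_in_expectation(self):
        sizes = []
        for rep in range(50):
            cmap = generate_categories(self.genes, {"neuron_projection": 40},
                                       planted_list=self.genes[:10],
                                       planted_fraction=0.2, seed=rep)
            sizes.append(len(cmap.genes_in("neuron_projection")))
        # expected: 10*0.2 + 190*0.2 = 40
        assert np.mean(sizes) == pytest.approx(40, rel=0.15)
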