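"""Calibration and recovery experiments on synthetic data.

These experiments measure the statistical behavior of the package's methods
under the planted-truth generator: type-I error of the MDC permutation test
under an exchangeable null, power to recover planted connectivity gains at
the gain classification rule, module recovery by adjusted Rand index, and
calibration/power of the module-behavior (NBF) correlation test. They are
used by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .connectivity import classify_mdc, mdc_test
from .matrix import ExpressionMatrix
from .network import CoexpressionModules, ModulePartition, module_eigengene
from .preprocess import filter_wgcna_genes, log2_transform
from .simulate import SimDesign, SimModuleSpec, generate_behavior, generate_design, generate_expression
from .traits import TraitVector, nbf_correlation


def _loading(rho: float) -> float:
    return float(np.sqrt(rho / (1.0 - rho)))


def _one_stratum_design(n_trials: int, seed: int) -> SimDesign:
    return SimDesign(n_trials=n_trials, regions=("AMP",), sexes=("M",), seed=seed)


def _simulate_module_groups(
    rho_e: float, rho_ref: float, n_genes: int, n_trials: int, seed: int,
    coupling: float = 0.0,
):
    """One planted module through the generator; returns the log2 matrix,
    partition, per-treatment sample lists, metadata and truth."""
    design = _one_stratum_design(n_trials, seed)
    mult_ref = _loading(rho_ref) / _loading(rho_e) if rho_e > 0 else 0.0
    spec = SimModuleSpec(
        "mod", n_genes, _loading(rho_e),
        {"E": 1.0, "NM": mult_ref, "NP": mult_ref},
        trait_coupling=coupling,
    )
    meta = generate_design(design)
    expr, truth = generate_expression(design, [spec], seed=seed, metadata=meta)
    logged = log2_transform(expr)
    part = ModulePartition(pd.Series(["mod"] * n_genes, index=logged.gene_ids))
    groups = {t: meta.loc[meta["treatment"] == t, "sample_id"].tolist()
              for t in ("E", "NM", "NP")}
    return logged, part, groups, meta, truth


def null_calibration_experiment(
    n_modules: int = 500,
    n_genes: int = 50,
    n_per_group: int = 10,
    rho: float = 0.3,
    M: int = 1000,
    seed: int = 0,
    scheme: str = "samples",
    alpha: float = 0.05,
) -> float:
    """Fraction of raw p_gain < alpha when both groups share one correlation
    structure (the exchangeable null); should sit near alpha."""
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_modules):
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        logged, part, groups, _, _ = _simulate_module_groups(
            rho, rho, n_genes, n_per_group, rep_seed)
        _, p_gain, _ = mdc_test(
            logged, part, "mod", groups["E"], groups["NM"],
            M=M, seed=rep_seed, scheme=scheme)
        hits += p_gain < alpha
    return hits / n_modules


def gain_recovery_experiment(
    n_replicates: int = 100,
    rho_e: float = 0.6,
    rho_ref: float = 0.3,
    n_genes: int = 50,
    n_per_group: int = 10,
    M: int = 1000,
    seed: int = 0,
    scheme: str = "samples",
) -> float:
    """Fraction of planted gain modules classified 'gain' (adjusted P < 0.05
    and MDC > 2, single-module family so adjusted = raw)."""
    ss = np.random.SeedSequence(seed + 1)
    gains = 0
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        logged, part, groups, _, _ = _simulate_module_groups(
            rho_e, rho_ref, n_genes, n_per_group, rep_seed)
        mdc_val, p_gain, p_loss = mdc_test(
            logged, part, "mod", groups["E"], groups["NM"],
            M=M, seed=rep_seed, scheme=scheme)
        gains += classify_mdc(mdc_val, p_gain, p_loss) == "gain"
    return gains / n_replicates


def module_recovery_experiment(
    n_modules: int = 4,
    genes_per_module: int = 50,
    rho: float = 0.6,
    n_samples: int = 30,
    seed: int = 0,
    **detector_params,
) -> float:
    """Adjusted Rand index between detected and planted module labels."""
    design = SimDesign(n_trials=max(2, n_samples // 3), regions=("AMP",),
                       sexes=("M",), seed=seed)
    specs = [
        SimModuleSpec(f"sim{i + 1}", genes_per_module, _loading(rho),
                      {"E": 1.0, "NM": 1.0, "NP": 1.0})
        for i in range(n_modules)
    ]
    meta = generate_design(design)
    expr, truth = generate_expression(design, specs, seed=seed, metadata=meta)
    regions = meta.set_index("sample_id").loc[expr.sample_ids, "region"].tolist()
    logged = log2_transform(filter_wgcna_genes(expr, regions))
    model = CoexpressionModules(**detector_params).fit(logged.data.T)
    truth_labels = truth.assignments.loc[logged.gene_ids].to_numpy()
    return float(adjusted_rand_score(truth_labels, model.labels_))


def nbf_null_experiment(
    n_replicates: int = 2000, n_samples: int = 10, seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Significance rate of the eigengene-frequency correlation when the
    trait is independent of the eigengene; should sit near alpha."""
    rng = np.random.default_rng(seed + 2)
    samples = [f"s{i}" for i in range(n_samples)]
    hits = 0
    for _ in range(n_replicates):
        scores = rng.standard_normal(n_samples)
        scores /= np.linalg.norm(scores)
        me = pd.Series(scores, index=samples)
        trait = TraitVector("fetch", pd.Series(rng.standard_normal(n_samples),
                                               index=samples))
        from .network import ModuleEigengene
        res = nbf_correlation(ModuleEigengene("mod", me, 0.9), trait, alpha=alpha)
        hits += res.significant
    return hits / n_replicates


def nbf_power_experiment(
    n_replicates: int = 200,
    coupling: float = 0.95,
    n_genes: int = 50,
    n_per_group: int = 10,
    behavior_noise_sd: float = 20.0,
    seed: int = 0,
) -> float:
    """Detection rate for a module planted with strong behavior coupling:
    the eigengene is computed from E-group expression and correlated with
    the generated frequency."""
    ss = np.random.SeedSequence(seed + 3)
    hits = 0
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        logged, part, groups, meta, truth = _simulate_module_groups(
            0.6, 0.6, n_genes, n_per_group, rep_seed, coupling=coupling)
        meta = generate_behavior(meta, truth, {"fetch_material_male": "mod"},
                                 noise_sd=behavior_noise_sd, seed=rep_seed)
        e_samples = groups["E"]
        me = module_eigengene(logged, part, "mod", e_samples)
        freqs = meta.set_index("sample_id").loc[e_samples, "fetch_material_male"]
        trait = TraitVector("fetch_material_male", freqs.astype(float))
        hits += nbf_correlation(me, trait).significant
    return hits / n_replicates
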