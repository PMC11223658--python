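"""Synthetic study generator: design, expression, behavior, categories.

The generator emulates the study design the downstream analyses assume:
10 trials x 3 treatments (E, NM, NP) x 2 sexes x 5 brain regions = 300
samples, with genes organized into latent co-expression modules.

Expression follows a one-factor-per-module model, independently per
(region, sex) stratum: gene g of module m in sample s has latent value
``loading_g(treatment(s)) * f_m(s) + eps`` with ``f_m(s)`` standard normal
and ``eps ~ N(0, noise_sd)``; ``loading_g(t) = base_loading *
connectivity_multiplier[t]``. The expected intra-module Pearson correlation
in treatment t is therefore ``loading(t)^2 / (loading(t)^2 + noise_sd^2)``,
which the returned ground truth records per module x treatment. Latent
values are emitted on a nonnegative TPM-like scale via the monotone map
``TPM = 2^(latent + shift) - 1`` (clipped at zero), so that the downstream
log2(TPM + 1) transform recovers the latent scale exactly wherever the shift
keeps values positive.

Behavior frequencies couple to module factors only in the E group; the
nonnesting groups draw near-zero frequencies. Category labels are planted
into chosen gene lists at a controlled rate for the over-representation
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .enrichment import PRIMARY_CATEGORIES, CategoryMap
from .matrix import ExpressionMatrix

DEFAULT_REGIONS = ("AMP", "SBN", "DNP", "PM", "Others")
DEFAULT_TREATMENTS = ("E", "NM", "NP")
DEFAULT_SEXES = ("M", "F")

#: actions carrying planted module-behavior coupling
COUPLED_ACTIONS = ("fetch_material_male", "stay_nestbox_male", "stay_nestbox_female")

LOG2_SHIFT = 8.0  # keeps the latent normal comfortably positive pre-exponentiation


@dataclass
class SimDesign:
    n_trials: int = 10
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    sexes: tuple[str, ...] = DEFAULT_SEXES
    regions: tuple[str, ...] = DEFAULT_REGIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise InvalidConfigError("n_trials must be >= 2")
        if not self.treatments or not self.regions or not self.sexes:
            raise InvalidConfigError("treatments, sexes and regions must be nonempty")

    @property
    def n_samples(self) -> int:
        return self.n_trials * len(self.treatments) * len(self.sexes) * len(self.regions)


@dataclass
class SimModuleSpec:
    module_id: str
    n_genes: int
    base_loading: float
    connectivity_multiplier: dict[str, float]
    trait_coupling: float = 0.0
    region_scope: tuple[str, ...] | None = None  # None = all regions

    def validate(self, design: SimDesign) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError(f"module {self.module_id}: n_genes must be >= 1")
        missing = set(design.treatments) - set(self.connectivity_multiplier)
        if missing:
            raise InvalidConfigError(
                f"module {self.module_id}: multiplier missing for treatment(s) {sorted(missing)}"
            )
        if any(v < 0 for v in self.connectivity_multiplier.values()):
            raise InvalidConfigError(f"module {self.module_id}: multipliers must be >= 0")
        if not -1.0 <= self.trait_coupling <= 1.0:
            raise InvalidConfigError(f"module {self.module_id}: trait_coupling outside [-1, 1]")

    def loading(self, treatment: str) -> float:
        return self.base_loading * self.connectivity_multiplier[treatment]

    def expected_correlation(self, treatment: str, noise_sd: float) -> float:
        l2 = self.loading(treatment) ** 2
        return l2 / (l2 + noise_sd**2)


@dataclass
class SimTruth:
    assignments: pd.Series  # gene -> module ('unassigned' for background)
    expected_correlation: dict[str, dict[str, float]]  # module -> treatment -> rho
    factors: pd.DataFrame  # samples x modules latent factor values
    trait_coupling: dict[str, float] = field(default_factory=dict)
    planted_categories: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignments": self.assignments.to_dict(),
            "expected_correlation": self.expected_correlation,
            "trait_coupling": self.trait_coupling,
            "planted_categories": self.planted_categories,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def generate_design(design: SimDesign) -> pd.DataFrame:
    """One metadata row per (trial, treatment, sex, region) combination.

    Treatments are exactly balanced within every (region, sex) stratum: each
    appears once per trial. Deterministic (and identical for equal configs).
    """
    rows = []
    for trial in range(1, design.n_trials + 1):
        for treatment in design.treatments:
            for sex in design.sexes:
                bird = f"T{trial:02d}{treatment}{sex}"
                for region in design.regions:
                    rows.append({
                        "sample_id": f"{bird}_{region}",
                        "bird_id": bird,
                        "sex": sex,
                        "region": region,
                        "treatment": treatment,
                        "trial": f"T{trial:02d}",
                    })
    return pd.DataFrame(rows)


def generate_expression(
    design: SimDesign,
    modules: list[SimModuleSpec],
    n_background_genes: int = 0,
    noise_sd: float = 1.0,
    seed: int | None = None,
    dropout_rate: float = 0.0,
    metadata: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Factor-model expression on a TPM-like scale plus ground truth."""
    if noise_sd <= 0:
        raise InvalidConfigError("noise_sd must be positive")
    if not 0.0 <= dropout_rate < 1.0:
        raise InvalidConfigError("dropout_rate must lie in [0, 1)")
    for spec in modules:
        spec.validate(design)
    ids = [spec.module_id for spec in modules]
    if len(set(ids)) != len(ids):
        raise InvalidConfigError("duplicate module ids in simulation spec")
    n_module_genes = sum(spec.n_genes for spec in modules)
    if n_module_genes + n_background_genes < 1:
        raise InvalidConfigError("simulation needs at least one gene")

    meta = metadata if metadata is not None else generate_design(design)
    rng = np.random.default_rng(design.seed if seed is None else seed)
    samples = meta["sample_id"].tolist()
    n_samples = len(samples)

    gene_ids: list[str] = []
    assignments: dict[str, str] = {}
    for spec in modules:
        for i in range(spec.n_genes):
            g = f"{spec.module_id}_g{i + 1:04d}"
            gene_ids.append(g)
            assignments[g] = spec.module_id
    for i in range(n_background_genes):
        g = f"bg_g{i + 1:05d}"
        gene_ids.append(g)
        assignments[g] = "unassigned"

    latent = rng.normal(0.0, noise_sd, size=(len(gene_ids), n_samples))
    factors = pd.DataFrame(0.0, index=samples, columns=ids)

    strata = meta.groupby(["region", "sex"], sort=True).indices
    sample_treatment = meta["treatment"].to_numpy()
    row0 = 0
    for spec in modules:
        rows = slice(row0, row0 + spec.n_genes)
        for (region, sex), idx in strata.items():
            f = rng.standard_normal(len(idx))
            in_scope = spec.region_scope is None or region in spec.region_scope
            factors.iloc[idx, factors.columns.get_loc(spec.module_id)] = f
            if not in_scope:
                continue
            loadings = np.array([spec.loading(t) for t in sample_treatment[idx]])
            latent[rows, idx] += loadings * f
        row0 += spec.n_genes

    tpm = np.maximum(np.exp2(latent + LOG2_SHIFT) - 1.0, 0.0)
    if dropout_rate > 0:
        tpm[rng.random(tpm.shape) < dropout_rate] = 0.0

    expr = ExpressionMatrix(pd.DataFrame(tpm, index=gene_ids, columns=samples), "tpm")
    truth = SimTruth(
        assignments=pd.Series(assignments),
        expected_correlation={
            spec.module_id: {
                t: spec.expected_correlation(t, noise_sd) for t in design.treatments
            }
            for spec in modules
        },
        factors=factors,
        trait_coupling={spec.module_id: spec.trait_coupling for spec in modules},
    )
    return expr, truth


def generate_behavior(
    metadata: pd.DataFrame,
    truth: SimTruth,
    couplings: dict[str, str],
    noise_sd: float = 0.0,
    seed: int | None = None,
    base: float = 600.0,
    scale: float = 200.0,
    nonnesting_scale: float = 5.0,
) -> pd.DataFrame:
    """Attach per-sample action frequencies (seconds/hour) to the metadata.

    ``couplings`` maps an action name to a module id; in E samples the
    frequency is an affine function of that module's latent factor (slope
    ``scale * trait_coupling``) plus Gaussian noise, clipped to [0, 3600].
    NM/NP samples draw near-zero frequencies (|N(0, nonnesting_scale)|).
    """
    rng = np.random.default_rng(seed)
    out = metadata.copy()
    known = set(truth.trait_coupling)
    for action, module_id in couplings.items():
        if module_id not in known:
            raise InvalidConfigError(f"unknown module id {module_id!r} for action {action!r}")
        coupling = truth.trait_coupling[module_id]
        f = truth.factors.loc[out["sample_id"], module_id].to_numpy()
        is_e = (out["treatment"] == "E").to_numpy()
        freq = np.abs(rng.normal(0.0, nonnesting_scale, size=len(out)))
        affine = base + scale * coupling * f[is_e]
        if noise_sd > 0:
            affine = affine + rng.normal(0.0, noise_sd, size=int(is_e.sum()))
        freq[is_e] = affine
        out[action] = np.clip(freq, 0.0, 3600.0)
    return out


def generate_categories(
    genes: list[str],
    category_sizes: dict[str, int],
    planted_list: list[str] | None = None,
    planted_fraction: float = 0.0,
    target_category: str = "neuron_projection",
    seed: int | None = None,
) -> CategoryMap:
    """Random category labels with an optional planted enrichment.

    Non-target categories draw ``category_sizes[cat]`` genes uniformly. For
    the target category, planted-list genes join with probability
    ``planted_fraction``; the rest of the gene pool joins at the background
    rate ``category_sizes[target] / len(genes)``.
    """
    genes = list(genes)
    gene_set = set(genes)
    planted = list(planted_list or [])
    if not set(planted) <= gene_set:
        missing = sorted(set(planted) - gene_set)
        raise InvalidConfigError(f"planted list contains unknown gene(s): {missing[:10]}")
    if not 0.0 <= planted_fraction <= 1.0:
        raise InvalidConfigError("planted_fraction must lie in [0, 1]")
    for cat, size in category_sizes.items():
        if cat not in PRIMARY_CATEGORIES:
            raise InvalidConfigError(f"unknown category {cat!r}")
        if size > len(genes):
            raise InvalidConfigError(f"category {cat!r} size {size} exceeds gene count")

    rng = np.random.default_rng(seed)
    cmap = CategoryMap()
    planted_set = set(planted)
    for cat, size in category_sizes.items():
        if cat == target_category:
            background_rate = size / len(genes)
            members = {g for g in planted if rng.random() < planted_fraction}
            members |= {g for g in genes if g not in planted_set
                        and rng.random() < background_rate}
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        cmap.memberships[cat] = members
    return cmap
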