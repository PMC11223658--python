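"""Config-driven orchestration of the full analysis.

``run`` executes synthetic-generate (or load) -> filter/log2 -> network ->
MDC -> module-behavior correlation + hubs -> over-representation ->
behavior comparisons, writing every stage's table plus a JSON manifest
(config hash, seeds, package version) to the output directory. Re-running
with the same config reproduces every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import mdc_scan
from .enrichment import module_over_representation
from .errors import InvalidConfigError, PipelineError
from .matrix import ExpressionMatrix, read_expression, read_metadata, validate_metadata
from .network import CoexpressionModules, module_eigengene, module_membership_all
from .preprocess import filter_wgcna_genes, log2_transform
from .simulate import (
    COUPLED_ACTIONS,
    SimDesign,
    SimModuleSpec,
    generate_behavior,
    generate_categories,
    generate_design,
    generate_expression,
)
from .traits import TraitVector, gene_significance, gs_quantile_threshold, nbf_scan, select_hub_genes

log = logging.getLogger("nestnet")


@dataclass
class SyntheticConfig:
    n_trials: int = 10
    regions: tuple[str, ...] = ("AMP", "SBN")
    sexes: tuple[str, ...] = ("M", "F")
    n_modules: int = 4
    genes_per_module: int = 50
    n_background_genes: int = 100
    module_correlation: float = 0.6  # constitutive modules, all treatments
    gain_correlation_e: float = 0.75  # differential module, E group
    gain_correlation_ref: float = 0.3  # differential module, NM/NP groups
    noise_sd: float = 1.0
    dropout_rate: float = 0.0
    trait_coupling: float = 0.9


@dataclass
class PipelineConfig:
    outdir: str = "nestnet_out"
    seed: int = 0
    expression_path: str | None = None
    metadata_path: str | None = None
    category_path: str | None = None
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    correlation: str = "bicor"
    beta: int = 6
    cut_height: float = 0.99
    min_module_size: int = 30
    comparisons: tuple[str, ...] = ("E-NM", "E-NP")
    n_permutations: int = 1000
    permutation_scheme: str = "samples"
    denom_floor: float = 0.1
    mm_threshold: float = 0.8
    gs_quantile: float = 0.99

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def digest(self) -> str:
        params = asdict(self)
        params.pop("outdir", None)  # a location, not an analysis parameter
        payload = json.dumps(params, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _loading(rho: float, noise_sd: float) -> float:
    """Loading giving an expected intra-module correlation rho."""
    if not 0.0 <= rho < 1.0:
        raise InvalidConfigError(f"correlation target must be in [0, 1), got {rho}")
    return float(noise_sd * np.sqrt(rho / (1.0 - rho)))


def build_synthetic_inputs(cfg: PipelineConfig):
    """Materialize the synthetic study: expression, metadata+behavior, categories, truth."""
    syn = cfg.synthetic
    design = SimDesign(n_trials=syn.n_trials, regions=tuple(syn.regions),
                       sexes=tuple(syn.sexes), seed=cfg.seed)
    base = _loading(syn.module_correlation, syn.noise_sd)
    gain_e = _loading(syn.gain_correlation_e, syn.noise_sd)
    gain_ref = _loading(syn.gain_correlation_ref, syn.noise_sd)
    modules = []
    for i in range(syn.n_modules):
        # first module gains connectivity in E and couples to behavior;
        # the rest keep the same structure in every treatment
        if i == 0:
            loading, coupling = gain_e, syn.trait_coupling
            mult = {"E": 1.0, "NM": gain_ref / gain_e, "NP": gain_ref / gain_e}
        else:
            loading, coupling = base, 0.0
            mult = {"E": 1.0, "NM": 1.0, "NP": 1.0}
        modules.append(SimModuleSpec(
            module_id=f"sim{i + 1}", n_genes=syn.genes_per_module,
            base_loading=loading, connectivity_multiplier=mult, trait_coupling=coupling,
        ))
    meta = generate_design(design)
    expr, truth = generate_expression(
        design, modules, n_background_genes=syn.n_background_genes,
        noise_sd=syn.noise_sd, seed=cfg.seed, dropout_rate=syn.dropout_rate,
        metadata=meta,
    )
    meta = generate_behavior(
        meta, truth, {a: "sim1" for a in COUPLED_ACTIONS},
        noise_sd=20.0, seed=cfg.seed + 1,
    )
    cmap = generate_categories(
        expr.gene_ids,
        {"neuron_projection": max(5, expr.n_genes // 20),
         "in_situ_neurogenesis": max(2, expr.n_genes // 50),
         "other_neurogenesis": max(5, expr.n_genes // 20)},
        planted_list=[g for g in expr.gene_ids if g.startswith("sim1_")],
        planted_fraction=0.5,
        seed=cfg.seed + 2,
    )
    return expr, meta, cmap, truth


def run(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "nestnet",
        "version": __version__,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "outputs": [],
    }

    def emit(name: str, df: pd.DataFrame, index=False, index_label=None) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index, index_label=index_label)
        manifest["outputs"].append(name)

    # ---- inputs ---------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.synthetic is not None and cfg.expression_path is None:
            expr, meta, cmap, truth = build_synthetic_inputs(cfg)
            truth.to_json(outdir / "truth.json")
            manifest["outputs"].append("truth.json")
            cmap.to_tsv(outdir / "categories.tsv")
            manifest["outputs"].append("categories.tsv")
        else:
            expr = read_expression(cfg.expression_path, scale="tpm")
            meta = read_metadata(cfg.metadata_path)
            from .enrichment import load_category_map
            cmap = load_category_map(cfg.category_path) if cfg.category_path else None
            truth = None
        meta = validate_metadata(meta)
        expr.to_tsv(outdir / "expression_tpm.tsv")
        manifest["outputs"].append("expression_tpm.tsv")
        emit("metadata.tsv", meta)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- preprocess -----------------------------------------------------
    stage = "preprocess"
    try:
        regions = meta.set_index("sample_id").loc[expr.sample_ids, "region"].tolist()
        filtered = filter_wgcna_genes(expr, regions)
        logged = log2_transform(filtered)
        log.info("preprocess: %d/%d genes retained", filtered.n_genes, expr.n_genes)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- network --------------------------------------------------------
    stage = "network"
    try:
        model = CoexpressionModules(
            correlation=cfg.correlation, beta=cfg.beta,
            cut_height=cfg.cut_height, min_module_size=cfg.min_module_size,
        ).fit(logged.data.T)
        part = model.partition_
        emit("modules.tsv", part.to_frame())
        emit("eigengenes.tsv", model.eigengenes_, index=True, index_label="sample_id")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- MDC ------------------------------------------------------------
    stage = "mdc"
    try:
        mdc_results = mdc_scan(
            logged, part, meta, comparisons=tuple(cfg.comparisons),
            M=cfg.n_permutations, seed=cfg.seed, scheme=cfg.permutation_scheme,
            denom_floor=cfg.denom_floor,
        )
        emit("mdc_results.tsv", mdc_results)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- NBF + hubs -----------------------------------------------------
    stage = "traits"
    try:
        meta_idx = meta.set_index("sample_id")
        action_cols = [c for c in meta.columns if c in COUPLED_ACTIONS]
        nbf_rows, hub_rows = [], []
        for (region, sex), grp in meta_idx.groupby(["region", "sex"], sort=True):
            e_samples = [s for s in grp.index
                         if grp.loc[s, "treatment"] == "E" and s in logged.data.columns]
            if len(e_samples) < 4 or not action_cols:
                continue
            mes = {}
            for module in part.modules:
                me = module_eigengene(logged, part, module, e_samples)
                mes[module] = me.scores
            me_frame = pd.DataFrame(mes, index=e_samples)
            freqs = grp.loc[e_samples, action_cols].astype(float)
            res = nbf_scan(me_frame, freqs)
            res.insert(0, "region", region)
            res.insert(1, "sex", sex)
            nbf_rows.append(res)

            sig = res[res["significant"]]
            for module in sig["module"].unique():
                trait_name = sig[sig["module"] == module].iloc[0]["trait"]
                trait = TraitVector(trait_name, freqs[trait_name])
                me = module_eigengene(logged, part, module, e_samples)
                members = part.members(module)
                mm = module_membership_all(logged.subset_samples(e_samples), me, members)
                gs = gene_significance(logged.subset_samples(e_samples), trait, members)
                thr = gs_quantile_threshold(gs.dropna(), cfg.gs_quantile)
                hubs = select_hub_genes(mm, gs, cfg.mm_threshold, thr, module=module)
                hubs.insert(0, "region", region)
                hubs.insert(1, "sex", sex)
                hub_rows.append(hubs.reset_index())
        emit("nbf_results.tsv", pd.concat(nbf_rows, ignore_index=True)
             if nbf_rows else pd.DataFrame(
                 columns=["region", "sex", "module", "trait", "r", "p", "significant", "n"]))
        emit("hub_genes.tsv", pd.concat(hub_rows, ignore_index=True)
             if hub_rows else pd.DataFrame(
                 columns=["region", "sex", "gene_id", "module", "MM", "GS",
                          "skipped", "is_hub"]))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- enrichment -----------------------------------------------------
    stage = "enrichment"
    try:
        if cmap is not None:
            enr = module_over_representation(part, cmap, logged.gene_ids)
            emit("module_enrichment.tsv", enr)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- behavior -------------------------------------------------------
    stage = "behavior"
    try:
        if action_cols:
            from .behavior import compare_treatments
            freq = (meta.drop_duplicates("bird_id").set_index("bird_id")[action_cols]
                    .astype(float))
            emit("behavior_comparisons.tsv", compare_treatments(freq, meta))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
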