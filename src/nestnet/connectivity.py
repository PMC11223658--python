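"""Modular differential connectivity (MDC) between treatment groups.

For a module X and two sample groups (nesting E versus a nonnesting
reference), each gene's intra-modular connectivity *kwithin* is the sum of
its Pearson correlations with all other module genes, computed within one
group's samples. The module-level statistic is

    MDC = sum(kwithin, E group) / sum(kwithin, reference group),

with MDC > 1 indicating a gain and MDC < 1 a loss of expression
connectivity in the nesting state. Significance comes from a permutation
null; given M permutations,

    p_gain = 1 - (1/M) * #{p : MDC_obs > MDC_p}
    p_loss = 1 - (1/M) * #{p : MDC_obs < MDC_p}

(strict inequalities). A module is classified "gain" when the BH-adjusted
p_gain < 0.05 and MDC > 2, "loss" when adjusted p_loss < 0.05 and
MDC < 0.5.

Three permutation schemes are available. The default, ``samples``, permutes
the group labels of the *samples* and recomputes the summed kwithin on each
permuted split — samples are the exchangeable unit under the null that both
groups share one expression distribution, and this scheme is calibrated.
The ``paired`` scheme (swap each gene's (kwithin_E, kwithin_ref) pair with
probability 1/2) and the ``pooled`` scheme (shuffle all 2G kwithin values)
permute the derived kwithin values instead; both are provided for
comparison but are anticonservative when module genes are correlated, which
is exactly the situation a co-expression module creates (see the methods
note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, InvalidConfigError
from .matrix import ExpressionMatrix
from .network import ModulePartition, pearson_rows

DEFAULT_DENOM_FLOOR = 0.1
PERMUTATION_SCHEMES = ("samples", "paired", "pooled")


@dataclass
class ConnectivityProfile:
    module: str
    group: str
    gene_ids: list[str]
    kwithin: np.ndarray
    n_samples: int

    @property
    def total(self) -> float:
        return float(self.kwithin.sum())


@dataclass
class MDCResult:
    module: str
    region: str | None
    sex: str | None
    comparison: str
    mdc: float
    p_gain: float
    p_loss: float
    adj_p_gain: float | None
    adj_p_loss: float | None
    classification: str
    n_permutations: int
    undefined: bool = False


def kwithin(
    m: ExpressionMatrix,
    part: ModulePartition,
    module: str,
    sample_ids: list[str],
    group: str = "",
) -> ConnectivityProfile:
    """Per-gene intra-modular connectivity within one group's samples."""
    genes = part.members(module)
    if len(genes) < 2:
        raise InvalidConfigError(f"module {module!r} needs >= 2 genes for kwithin")
    if len(sample_ids) < 3:
        raise InvalidConfigError("kwithin needs >= 3 samples in the group")
    X = m.data.loc[genes, sample_ids].to_numpy(dtype=float)
    C, constant = pearson_rows(X)
    if constant.any():
        warnings.warn(
            f"module {module}: {int(constant.sum())} constant gene(s) in group "
            f"{group or '?'}; their correlations count as 0",
            stacklevel=2,
        )
    np.fill_diagonal(C, 0.0)
    return ConnectivityProfile(module, group, genes, C.sum(axis=1), len(sample_ids))


def mdc(
    profile_e: ConnectivityProfile,
    profile_ref: ConnectivityProfile,
    denom_floor: float = DEFAULT_DENOM_FLOOR,
) -> float:
    """MDC ratio; NaN when the reference kwithin sum is below the floor."""
    if profile_e.module != profile_ref.module:
        raise InvalidConfigError("profiles come from different modules")
    if profile_e.gene_ids != profile_ref.gene_ids:
        raise InvalidConfigError("profiles cover different gene sets")
    denom = profile_ref.total
    if abs(denom) < denom_floor:
        return float("nan")
    return profile_e.total / denom


def _p_from_counts(n_gt: int, n_lt: int, m_eff: int, plus_one: bool) -> tuple[float, float]:
    if plus_one:
        p_gain = 1.0 - n_gt / (m_eff + 1.0)
        p_loss = 1.0 - n_lt / (m_eff + 1.0)
    else:
        p_gain = 1.0 - n_gt / m_eff
        p_loss = 1.0 - n_lt / m_eff
    return float(np.clip(p_gain, 0.0, 1.0)), float(np.clip(p_loss, 0.0, 1.0))


def _check_permutation_count(M: int) -> None:
    if M < 1:
        raise InvalidConfigError("number of permutations must be positive")
    if M < 100:
        warnings.warn(f"M={M} permutations is small; P-value resolution is 1/{M}",
                      stacklevel=3)


def _finalize(mdc_obs: float, mdc_perm: np.ndarray, M: int, plus_one: bool):
    defined = np.isfinite(mdc_perm)
    n_undef = int(M - defined.sum())
    if n_undef > 0.01 * M:
        raise FormatError(
            f"MDC undefined in {n_undef}/{M} permutations (> 1%); "
            "denominator too close to zero for a meaningful test"
        )
    vals = mdc_perm[defined]
    m_eff = vals.size
    return _p_from_counts(int((mdc_obs > vals).sum()), int((mdc_obs < vals).sum()),
                          m_eff, plus_one)


def mdc_permutation_test(
    profile_e: ConnectivityProfile,
    profile_ref: ConnectivityProfile,
    M: int = 10_000,
    seed: int | np.random.Generator | None = None,
    scheme: str = "paired",
    denom_floor: float = DEFAULT_DENOM_FLOOR,
    plus_one: bool = False,
) -> tuple[float, float]:
    """Permutation p-values computed from the kwithin profiles alone.

    Schemes: ``paired`` swaps each gene's (kwithin_E, kwithin_ref) pair
    independently with probability 1/2; ``pooled`` reassigns the pooled 2G
    values at random. For the calibrated sample-label permutation, which
    needs the expression matrix, use :func:`mdc_test`.
    """
    if scheme not in ("paired", "pooled"):
        raise InvalidConfigError(
            f"profile-level permutation supports 'paired'/'pooled', got {scheme!r}"
        )
    if profile_e.gene_ids != profile_ref.gene_ids:
        raise InvalidConfigError("profiles cover different gene sets")
    _check_permutation_count(M)
    rng = np.random.default_rng(seed)
    ke, kr = profile_e.kwithin, profile_ref.kwithin
    mdc_obs = mdc(profile_e, profile_ref, denom_floor)
    if not np.isfinite(mdc_obs):
        raise FormatError("observed MDC is undefined (denominator below floor)")
    G = ke.size
    if scheme == "paired":
        swap = rng.random((M, G)) < 0.5
        d = kr - ke
        sums_e = ke.sum() + swap @ d
        sums_r = kr.sum() - swap @ d
    else:  # pooled
        pool = np.concatenate([ke, kr])
        total = pool.sum()
        sums_e = np.empty(M)
        for p in range(M):
            take = rng.permutation(2 * G)[:G]
            sums_e[p] = pool[take].sum()
        sums_r = total - sums_e
    with np.errstate(divide="ignore", invalid="ignore"):
        mdc_perm = np.where(np.abs(sums_r) < denom_floor, np.nan, sums_e / sums_r)
    return _finalize(mdc_obs, mdc_perm, M, plus_one)


def _standardized_ksum(X: np.ndarray) -> float:
    """Sum of off-diagonal Pearson correlations of the rows of X.

    Equal to ||sum of unit-normalized centered rows||^2 minus the number of
    non-constant rows; constant rows contribute zero, matching kwithin's
    treat-as-zero rule.
    """
    Z = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.square(Z).sum(axis=1))
    nz = norms > 0
    Z[nz] /= norms[nz, None]
    Z[~nz] = 0.0
    s = Z.sum(axis=0)
    return float(s @ s - nz.sum())


def _batched_ksum(T: np.ndarray) -> np.ndarray:
    """_standardized_ksum over a (batch, genes, samples) stack."""
    Z = T - T.mean(axis=2, keepdims=True)
    norms = np.sqrt(np.square(Z).sum(axis=2, keepdims=True))
    valid = norms[..., 0] > 0
    Z = np.divide(Z, norms, out=np.zeros_like(Z), where=norms > 0)
    s = Z.sum(axis=1)  # (batch, samples)
    return np.square(s).sum(axis=1) - valid.sum(axis=1)


def mdc_test(
    m: ExpressionMatrix,
    part: ModulePartition,
    module: str,
    samples_e: list[str],
    samples_ref: list[str],
    M: int = 10_000,
    seed: int | np.random.Generator | None = None,
    scheme: str = "samples",
    denom_floor: float = DEFAULT_DENOM_FLOOR,
    plus_one: bool = False,
    chunk: int = 256,
) -> tuple[float, float, float]:
    """Full MDC test for one module: returns (mdc, p_gain, p_loss).

    With the default ``samples`` scheme the group labels of the pooled
    samples are permuted and the summed kwithin recomputed on every split.
    """
    if scheme not in PERMUTATION_SCHEMES:
        raise InvalidConfigError(f"unknown permutation scheme {scheme!r}")
    prof_e = kwithin(m, part, module, samples_e, group="E")
    prof_r = kwithin(m, part, module, samples_ref, group="ref")
    mdc_obs = mdc(prof_e, prof_r, denom_floor)
    if not np.isfinite(mdc_obs):
        return mdc_obs, float("nan"), float("nan")
    if scheme in ("paired", "pooled"):
        p_gain, p_loss = mdc_permutation_test(
            prof_e, prof_r, M=M, seed=seed, scheme=scheme,
            denom_floor=denom_floor, plus_one=plus_one,
        )
        return mdc_obs, p_gain, p_loss

    _check_permutation_count(M)
    rng = np.random.default_rng(seed)
    genes = part.members(module)
    Z = m.data.loc[genes, list(samples_e) + list(samples_ref)].to_numpy(dtype=float)
    n_e, n_tot = len(samples_e), Z.shape[1]
    mdc_perm = np.empty(M)
    done = 0
    while done < M:
        b = min(chunk, M - done)
        idx = np.argsort(rng.random((b, n_tot)), axis=1)  # b random permutations
        P = Z[:, idx]             # (genes, b, n_tot)
        P = np.swapaxes(P, 0, 1)  # (b, genes, n_tot)
        se = _batched_ksum(P[:, :, :n_e])
        sr = _batched_ksum(P[:, :, n_e:])
        with np.errstate(divide="ignore", invalid="ignore"):
            mdc_perm[done:done + b] = np.where(np.abs(sr) < denom_floor, np.nan, se / sr)
        done += b
    p_gain, p_loss = _finalize(mdc_obs, mdc_perm, M, plus_one)
    return mdc_obs, p_gain, p_loss


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise InvalidConfigError("empty P-value list")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidConfigError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_mdc(
    mdc_value: float,
    adj_p_gain: float,
    adj_p_loss: float,
    gain_mdc: float = 2.0,
    loss_mdc: float = 0.5,
    alpha: float = 0.05,
) -> str:
    """'gain' iff adjusted p_gain < alpha and MDC > 2; 'loss' iff adjusted
    p_loss < alpha and MDC < 0.5; otherwise 'none'. Undefined MDC -> 'none'."""
    if not np.isfinite(mdc_value):
        return "none"
    if adj_p_gain < alpha and mdc_value > gain_mdc:
        return "gain"
    if adj_p_loss < alpha and mdc_value < loss_mdc:
        return "loss"
    return "none"


def mdc_scan(
    m: ExpressionMatrix,
    part: ModulePartition,
    metadata: pd.DataFrame,
    comparisons: tuple[str, ...] = ("E-NM", "E-NP"),
    M: int = 10_000,
    seed: int | None = None,
    scheme: str = "samples",
    denom_floor: float = DEFAULT_DENOM_FLOOR,
    min_module_size_for_test: int = 2,
) -> pd.DataFrame:
    """MDC over all modules x (region, sex) strata x comparisons.

    BH adjustment is applied within each (stratum, comparison, direction)
    family across its modules. Returns a tidy results table.
    """
    ss = np.random.SeedSequence(seed)
    rows: list[MDCResult] = []
    meta = metadata.set_index("sample_id")
    combos = sorted(set(zip(meta["region"], meta["sex"])))
    for (region, sex) in combos:
        in_stratum = meta[(meta["region"] == region) & (meta["sex"] == sex)]
        for comparison in comparisons:
            ref_grp = comparison.split("-")[1]
            samples_e = [s for s in in_stratum.index if in_stratum.loc[s, "treatment"] == "E"
                         and s in m.data.columns]
            samples_r = [s for s in in_stratum.index
                         if in_stratum.loc[s, "treatment"] == ref_grp and s in m.data.columns]
            fam: list[MDCResult] = []
            for module in part.modules:
                if len(part.members(module)) < min_module_size_for_test:
                    continue
                sub_seed = np.random.default_rng(ss.spawn(1)[0])
                mdc_val, p_gain, p_loss = mdc_test(
                    m, part, module, samples_e, samples_r,
                    M=M, seed=sub_seed, scheme=scheme, denom_floor=denom_floor,
                )
                fam.append(MDCResult(
                    module=module, region=region, sex=sex, comparison=comparison,
                    mdc=mdc_val, p_gain=p_gain, p_loss=p_loss,
                    adj_p_gain=None, adj_p_loss=None, classification="none",
                    n_permutations=M, undefined=not np.isfinite(mdc_val),
                ))
            defined = [r for r in fam if not r.undefined]
            if defined:
                adj_g = bh_adjust([r.p_gain for r in defined])
                adj_l = bh_adjust([r.p_loss for r in defined])
                for r, ag, al in zip(defined, adj_g, adj_l):
                    r.adj_p_gain, r.adj_p_loss = float(ag), float(al)
                    r.classification = classify_mdc(r.mdc, ag, al)
            rows.extend(fam)
    return pd.DataFrame([vars(r) for r in rows])
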