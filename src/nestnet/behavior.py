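"""Action frequencies and behavioral comparisons.

Behavior is annotated per one-second window over an 80-minute recording
(shortened recordings are normalized by the seconds actually recorded), and
summarized as the number of seconds each action occurred per hour. Treatment
groups are compared per action and sex with two-sided Mann-Whitney U tests —
exact by enumeration when both groups have at most 8 observations, the
normal approximation with tie correction otherwise — and BH adjustment over
the family of all actions x all three treatment pairs within a sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError
from .connectivity import bh_adjust
from .traits import pearson_test

#: the annotated action vocabulary
ACTIONS = (
    "fetch_material",
    "stay_nestbox",
    "upright_fluffed_singing",
    "copulating",
    "beak_wiping",
    "allopreening",
    "autopreening",
    "tail_quivering",
    "beak_fencing",
    "feeding",
    "drinking",
)

MAX_RECORDING_SECONDS = 4800  # 80 minutes
EXACT_MAX_N = 8

TREATMENT_PAIRS = (("E", "NM"), ("E", "NP"), ("NM", "NP"))


@dataclass
class ActionRecord:
    bird_id: str
    action: str
    indicators: np.ndarray  # 0/1 per second

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicators)
        if not np.isin(ind, (0, 1)).all():
            raise InvalidConfigError("per-second indicators must be 0/1")
        if ind.size > MAX_RECORDING_SECONDS:
            raise InvalidConfigError(
                f"recording longer than {MAX_RECORDING_SECONDS} s ({ind.size} s)"
            )
        self.indicators = ind.astype(int)

    @property
    def recording_seconds(self) -> int:
        return int(self.indicators.size)


def action_frequency(rec: ActionRecord) -> float:
    """Seconds per hour the action occurred, normalized by recorded seconds."""
    if rec.recording_seconds == 0:
        raise InvalidConfigError(f"zero-length recording for bird {rec.bird_id!r}")
    return float(rec.indicators.sum() * 3600.0 / rec.recording_seconds)


def frequency_table(records: list[ActionRecord]) -> pd.DataFrame:
    """Bird x action table of frequencies (seconds/hour)."""
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        rows.setdefault(rec.bird_id, {})[rec.action] = action_frequency(rec)
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney U by full enumeration (handles ties).

    Enumerates all C(n+m, n) assignments of the pooled values to the two
    groups; the two-sided P is the fraction of assignments whose U deviates
    from the null mean nm/2 at least as much as the observed U.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise InvalidConfigError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks handle ties
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    combs = np.array(list(combinations(range(n + m), n)))
    u_all = ranks[combs].sum(axis=1) - n * (n + 1) / 2.0
    center = n * m / 2.0
    dev = abs(u_obs - center)
    p = float(np.mean(np.abs(u_all - center) >= dev - 1e-12))
    return float(u_obs), p


def mann_whitney(a, b) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U; exact enumeration when both n <= 8.

    Returns (U, p, all_tied). Identical constant groups yield P = 1 with the
    tie flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidConfigError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0, True
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        u, p = mann_whitney_exact(a, b)
        return u, p, False
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), False


def compare_treatments(
    freq: pd.DataFrame,
    metadata: pd.DataFrame,
    actions=None,
    sexes=("M", "F"),
    pairs=TREATMENT_PAIRS,
) -> pd.DataFrame:
    """Mann-Whitney comparisons of action frequencies between treatment pairs.

    ``freq`` is a bird x action table; ``metadata`` must map bird_id to sex
    and treatment (one row per bird suffices; duplicated bird rows are
    deduplicated). BH adjustment is applied within each sex over all actions
    x treatment pairs.
    """
    actions = list(actions) if actions is not None else list(freq.columns)
    birds = metadata.drop_duplicates("bird_id").set_index("bird_id")
    rows = []
    for sex in sexes:
        fam = []
        for action in actions:
            for ga, gb in pairs:
                ids_a = [b for b in freq.index
                         if b in birds.index and birds.loc[b, "sex"] == sex
                         and birds.loc[b, "treatment"] == ga]
                ids_b = [b for b in freq.index
                         if b in birds.index and birds.loc[b, "sex"] == sex
                         and birds.loc[b, "treatment"] == gb]
                if not ids_a or not ids_b:
                    continue
                u, p, tied = mann_whitney(freq.loc[ids_a, action], freq.loc[ids_b, action])
                fam.append({
                    "sex": sex, "action": action, "group_a": ga, "group_b": gb,
                    "n_a": len(ids_a), "n_b": len(ids_b),
                    "U": u, "p": p, "all_tied": tied,
                })
        if fam:
            adj = bh_adjust([r["p"] for r in fam])
            for r, ap in zip(fam, adj):
                r["adj_p"] = float(ap)
        rows.extend(fam)
    return pd.DataFrame(rows)


def material_usage_correlation(
    usage: pd.Series,
    freq: pd.Series,
    exclude=("R5",),
) -> tuple[float, float, list[str]]:
    """Pearson correlation between nest-material usage (grams per pair) and an
    action frequency over E-group pairs, after dropping excluded pairs.

    Returns (r, p, dropped_ids); r is NaN when usage or frequency is constant.
    """
    common = usage.index.intersection(freq.index)
    dropped = [i for i in common if i in set(exclude)]
    keep = [i for i in common if i not in set(exclude)]
    if len(keep) < 4:
        raise InvalidConfigError(f"need >= 4 pairs after exclusions, got {len(keep)}")
    r, p = pearson_test(usage.loc[keep].to_numpy(), freq.loc[keep].to_numpy())
    return r, p, dropped
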