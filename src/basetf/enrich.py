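"""Gene functional enrichment by the two-sample Wilcoxon rank-sum test.

Genes are ranked by their signed log-fold change d and, for each gene set,
the ranks of in-set genes are compared with the ranks of the remaining
genes. The up-side p-value asks whether in-set ranks are larger than
exchangeability allows (the set concentrates among up-regulated genes); the
down-side p-value asks the opposite. Both one-sided tests are computed
independently for every set, so the companion of an extreme p on one side
is typically a p near 1 on the other. No differential-expression cutoff is
required — this is the cutoff-free alternative to the Fisher-exact
contingency approach, which is retained as an optional secondary mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DifferentiationProfile, GeneSetCollection

logger = logging.getLogger("basetf")

__all__ = ["EnrichmentResult", "wilcoxon_enrichment", "fisher_enrichment"]

# below this in-set size (and absent ties) the exact rank-sum distribution
# is used; otherwise the normal approximation with continuity and tie
# correction
EXACT_MAX_IN_SET = 10


@dataclass
class EnrichmentResult:
    set_name: str
    direction: str
    p_value: float
    n_in_set: int
    n_out_set: int
    rank_sum_statistic: float

    def __post_init__(self) -> None:
        if self.n_in_set < 1:
            raise ValueError("n_in_set must be >= 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _one_set(
    d: np.ndarray, ranks: np.ndarray, in_mask: np.ndarray, direction: str
) -> tuple[float, float]:
    """One-sided rank-sum p for in-set genes vs the rest, plus the statistic."""
    x = d[in_mask]
    y = d[~in_mask]
    alternative = "greater" if direction == "up" else "less"
    n_in = x.size
    has_ties = np.unique(d).size < d.size
    method = "exact" if (n_in < EXACT_MAX_IN_SET and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    rank_sum = float(ranks[in_mask].sum())
    return float(res.pvalue), rank_sum


def wilcoxon_enrichment(
    profile: DifferentiationProfile,
    sets: GeneSetCollection,
    direction: str = "both",
) -> list[EnrichmentResult]:
    """Rank-sum enrichment of every gene set against the differentiation profile.

    Sets are intersected with the profile's genes; sets with fewer than two
    members present, or covering every gene (no out-group), are skipped with
    a log entry. Results are sorted by p-value within each direction.
    """
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    directions = ("up", "down") if direction == "both" else (direction,)
    for dirn in directions:
        if dirn not in ("up", "down"):
            raise ValueError(f"direction must be 'up', 'down' or 'both', got {dirn!r}")
    gene_pos = {g: i for i, g in enumerate(profile.gene_ids)}
    d = profile.d
    ranks = stats.rankdata(d, method="average")
    results: list[EnrichmentResult] = []
    for name, (_desc, members) in sets:
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if len(idx) < 2:
            logger.info("set %s: fewer than 2 members in profile, skipped", name)
            continue
        if len(idx) == len(d):
            logger.info("set %s: covers all genes (no out-group), skipped", name)
            continue
        in_mask = np.zeros(d.size, dtype=bool)
        in_mask[idx] = True
        for dirn in directions:
            p, rank_sum = _one_set(d, ranks, in_mask, dirn)
            results.append(
                EnrichmentResult(
                    set_name=name,
                    direction=dirn,
                    p_value=p,
                    n_in_set=int(in_mask.sum()),
                    n_out_set=int((~in_mask).sum()),
                    rank_sum_statistic=rank_sum,
                )
            )
    results.sort(key=lambda r: (r.direction, r.p_value, r.set_name))
    return results


def fisher_enrichment(
    profile: DifferentiationProfile,
    sets: GeneSetCollection,
    cutoff: float,
    direction: str = "up",
) -> list[EnrichmentResult]:
    """Threshold-based Fisher-exact enrichment (secondary, for comparison).

    Genes with directional log-fold change above ``cutoff`` are called
    differentially expressed and tested for association with set membership
    in a 2x2 table. The result depends on the cutoff choice — the rank-sum
    test above avoids exactly that dependence.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    de_mask = profile.direction(direction) > cutoff
    gene_pos = {g: i for i, g in enumerate(profile.gene_ids)}
    results = []
    for name, (_desc, members) in sets:
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if len(idx) < 2 or len(idx) == len(profile):
            continue
        in_mask = np.zeros(len(profile), dtype=bool)
        in_mask[idx] = True
        table = [
            [int((in_mask & de_mask).sum()), int((in_mask & ~de_mask).sum())],
            [int((~in_mask & de_mask).sum()), int((~in_mask & ~de_mask).sum())],
        ]
        _odds, p = stats.fisher_exact(table, alternative="greater")
        results.append(
            EnrichmentResult(
                set_name=name,
                direction=direction,
                p_value=float(p),
                n_in_set=int(in_mask.sum()),
                n_out_set=int((~in_mask).sum()),
                rank_sum_statistic=float(table[0][0]),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Wide table: one row per set with p_up, p_down and the direction call."""
    rows: dict[str, dict] = {}
    for r in results:
        row = rows.setdefault(
            r.set_name, {"set_name": r.set_name, "n_in_set": r.n_in_set}
        )
        row[f"p_{r.direction}"] = r.p_value
    frame = pd.DataFrame(list(rows.values()))
    if {"p_up", "p_down"} <= set(frame.columns):
        frame["direction"] = np.where(frame["p_up"] <= frame["p_down"], "up", "down")
        frame["_minp"] = frame[["p_up", "p_down"]].min(axis=1)
        frame = frame.sort_values("_minp", kind="stable").drop(columns="_minp")
    return frame.reset_index(drop=True)
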