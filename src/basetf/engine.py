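"""The BASE statistic: sorted differentiation, weighted CDFs, permutation null.

For one regulation direction, genes are sorted by decreasing directional
log-fold change d (d+ for up-regulation, d- for down). Two cumulative
functions are formed over the sorted genes,

    f0(i) = sum_{j<=i} d_pi(j)          / sum_j d_pi(j)
    f1(i) = sum_{j<=i} d_pi(j) b_pi(j)  / sum_j d_pi(j) b_pi(j)

where b is the binding-strength vector of one factor (here: promoter motif
counts tau, by the Bernoulli binding model's cancellation argument). The
BASE score is the maximum gap delta = max_i [f1(i) - f0(i)]: a factor whose
binding weight concentrates on strongly differentiated genes pulls f1 ahead
of f0. Significance comes from re-pairing b with genes by uniform random
permutation; the p-value is the fraction of permuted scores strictly
exceeding the observed one.

Both cumulative functions use the directional vector d_dir. The raw signed
d would make f0 non-monotone over genes whose directional component is zero
and would break the identity "constant weights imply delta = 0"; a
``literal_f0`` escape hatch reproduces the signed-d variant for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _all_permutations
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .core import (
    BaseResult,
    BindingCountMatrix,
    DifferentiationProfile,
    ExpressionPair,
)

logger = logging.getLogger("basetf")

__all__ = [
    "DegenerateDirectionError",
    "diff_expression",
    "base_cdfs",
    "base_score",
    "permutation_pvalue",
    "run_base",
    "adjust_fdr",
]

# guards floating-point noise in the strict comparison delta* > delta;
# all attainable score gaps differ by far more than this at double precision
_SCORE_TOL = 1e-12

_EXACT_MAX_N = 8


class DegenerateDirectionError(ValueError):
    """Raised when a direction carries no differentiation or no weight."""


def diff_expression(pair: ExpressionPair) -> DifferentiationProfile:
    """Natural-log fold changes d = ln(e1/e0), dropping nonpositive genes.

    Genes with a nonpositive abundance in either sample cannot enter the
    logarithm and are removed (the number dropped is logged).
    """
    keep = (pair.e0 > 0) & (pair.e1 > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("diff_expression: dropped %d genes with nonpositive abundance", n_drop)
    if not keep.any():
        raise ValueError("all genes have nonpositive abundance in one sample")
    gene_ids = [g for g, k in zip(pair.gene_ids, keep) if k]
    d = np.log(pair.e1[keep] / pair.e0[keep])
    return DifferentiationProfile(gene_ids=gene_ids, d=d)


def _sort_descending(d_dir: np.ndarray) -> np.ndarray:
    """Stable descending order (ties keep original index order)."""
    return np.argsort(-d_dir, kind="stable")


def base_cdfs(
    d_dir: np.ndarray,
    b: np.ndarray,
    literal_f0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """The two cumulative functions over genes sorted by decreasing d_dir.

    Parameters
    ----------
    d_dir
        Nonnegative directional differentiation (d+ or d-).
    b
        Nonnegative binding-strength vector, same length.
    literal_f0
        If given, the vector accumulated in f0 instead of ``d_dir`` (the
        signed-d reading of the published formula); sorting is always by
        ``d_dir``.

    Returns
    -------
    (f0, f1), both nondecreasing with last element 1.
    """
    d_dir = np.asarray(d_dir, dtype=float)
    b = np.asarray(b, dtype=float)
    if d_dir.shape != b.shape or d_dir.ndim != 1:
        raise ValueError("d_dir and b must be 1-D of equal length")
    if np.any(d_dir < 0) or np.any(b < 0):
        raise ValueError("d_dir and b must be nonnegative")
    total = d_dir.sum()
    if total <= 0:
        raise DegenerateDirectionError("no differentiation in this direction")
    wtotal = float(d_dir @ b)
    if wtotal <= 0:
        raise DegenerateDirectionError("motif has no weight on differentiated genes")
    order = _sort_descending(d_dir)
    f0_src = d_dir if literal_f0 is None else np.asarray(literal_f0, float)
    f0 = np.cumsum(f0_src[order])
    f0 /= f0[-1]
    f1 = np.cumsum(d_dir[order] * b[order])
    f1 /= f1[-1]
    return f0, f1


def base_score(f0: np.ndarray, f1: np.ndarray) -> float:
    """BASE score delta = max_i [f1(i) - f0(i)]."""
    f0 = np.asarray(f0, float)
    f1 = np.asarray(f1, float)
    if f0.shape != f1.shape:
        raise ValueError("f0 and f1 must have equal length")
    return float(np.max(f1 - f0))


@dataclass
class PermutationResult:
    p_value: float
    delta: float
    null_scores: np.ndarray
    exact: bool = False


def _tie_block_ends(d_sorted: np.ndarray) -> np.ndarray:
    """Indices closing each run of tied values in the sorted vector.

    The running gap f1 - f0 is evaluated only at these indices: inside a
    tied block the partial sums depend on the arbitrary order of the tied
    entries, so the literal per-index maximum would make both the observed
    score and its exact permutation p-value depend on input order. At
    block ends the partial sums are order-free, and with all-distinct d
    every index is a block end, recovering the plain maximum.
    """
    n = d_sorted.size
    ends = np.nonzero(np.diff(d_sorted) != 0)[0]
    return np.append(ends, n - 1)


def _null_scores_sampled(
    d_sorted: np.ndarray,
    b_sorted: np.ndarray,
    f0: np.ndarray,
    eval_idx: np.ndarray,
    K: int,
    rng: np.random.Generator,
    chunk_elems: int = 20_000_000,
) -> np.ndarray:
    """Scores under K uniform re-pairings of b with the sorted genes.

    Vectorised: each row of a (K, N) matrix is an independent permutation of
    b; the cumulative weighted sums are formed in one pass. Chunked to bound
    memory on large gene sets.
    """
    n = d_sorted.size
    f0_eval = f0[eval_idx]
    out = np.empty(K)
    chunk = max(1, min(K, chunk_elems // max(n, 1)))
    done = 0
    while done < K:
        k = min(chunk, K - done)
        perm = np.broadcast_to(b_sorted, (k, n)).copy()
        rng.permuted(perm, axis=1, out=perm)
        cum = np.cumsum(perm * d_sorted, axis=1)
        tot = cum[:, -1].copy()
        degenerate = tot <= 0
        tot[degenerate] = 1.0
        scores = np.max(cum[:, eval_idx] / tot[:, None] - f0_eval, axis=1)
        scores[degenerate] = 0.0
        out[done : done + k] = scores
        done += k
    return out


def _null_scores_exact(
    d_sorted: np.ndarray,
    b_sorted: np.ndarray,
    f0: np.ndarray,
    eval_idx: np.ndarray,
) -> np.ndarray:
    n = d_sorted.size
    if n > _EXACT_MAX_N:
        raise ValueError(f"exact mode enumerates N! pairings; N <= {_EXACT_MAX_N} required")
    f0_eval = f0[eval_idx]
    scores = []
    for perm in _all_permutations(range(n)):
        w = np.cumsum(d_sorted * b_sorted[list(perm)])
        if w[-1] <= 0:
            scores.append(0.0)
        else:
            scores.append(float(np.max(w[eval_idx] / w[-1] - f0_eval)))
    return np.asarray(scores)


def permutation_pvalue(
    d_dir: np.ndarray,
    b: np.ndarray,
    K: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    exact: bool = False,
    add_one: bool = False,
) -> PermutationResult:
    """Observed BASE score and its permutation p-value.

    The p-value is the fraction of null scores strictly greater than the
    observed delta, ``p = #{delta* > delta} / K``. With ``add_one`` the
    estimate ``(1 + #) / (1 + K)`` is returned instead, which cannot be
    zero. ``exact`` enumerates all N! pairings (N <= 8) in place of random
    sampling; K is then ignored.

    When d_dir contains ties, the gap is evaluated at the end of each tied
    block (see :func:`_tie_block_ends`), so the score and its exact p-value
    do not depend on the input order of tied genes; with distinct values
    this coincides with the plain maximum over all indices.
    """
    d_dir = np.asarray(d_dir, float)
    b = np.asarray(b, float)
    f0, f1 = base_cdfs(d_dir, b)
    order = _sort_descending(d_dir)
    d_sorted = d_dir[order]
    b_sorted = b[order]
    eval_idx = _tie_block_ends(d_sorted)
    delta = float(np.max((f1 - f0)[eval_idx]))
    if exact:
        null = _null_scores_exact(d_sorted, b_sorted, f0, eval_idx)
    else:
        if K < 1:
            raise ValueError("K must be >= 1")
        rng = np.random.default_rng(seed)
        null = _null_scores_sampled(d_sorted, b_sorted, f0, eval_idx, K, rng)
    exceed = int(np.count_nonzero(null > delta + _SCORE_TOL))
    if add_one:
        p = (1 + exceed) / (1 + null.size)
    else:
        p = exceed / null.size
    return PermutationResult(p_value=p, delta=delta, null_scores=null, exact=exact)


def _rank_weights(x: np.ndarray) -> np.ndarray:
    """Average ranks (ties share their mean rank; zeros keep rank mass)."""
    return rankdata(x, method="average")


def _motif_key(motif_id: str) -> int:
    """Stable 31-bit key from the motif identifier.

    Seeding each (motif, direction) stream from (master seed, motif key)
    rather than the column position makes per-motif results independent of
    the order in which motifs appear in the count matrix.
    """
    import hashlib

    digest = hashlib.sha256(motif_id.encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def run_base(
    profile: DifferentiationProfile,
    counts: BindingCountMatrix,
    K: int = 10_000,
    seed: int = 0,
    rank_based: bool = False,
    exact: bool = False,
    fdr: str = "bh",
    add_one: bool = False,
    motif_factors: dict[str, str] | None = None,
) -> list[BaseResult]:
    """Run the full inference: every motif, both directions, FDR per direction.

    Genes are matched by the intersection of the profile and the count
    matrix (inner join; the discarded counts are logged). Each (motif,
    direction) pair receives its own reproducible random stream derived from
    the master ``seed`` and the motif's identifier, so results do not
    depend on evaluation order or on the column layout of the matrix. Degenerate cases are kept in the output with
    delta = 0, p = 1 and an explanatory flag rather than dropped, so the
    ranking over motifs stays total.

    With ``rank_based``, both the directional differentiation vector and the
    binding vector are replaced by their average ranks before scoring — the
    robust variant, invariant under strictly increasing transforms of d.
    """
    common = [g for g in profile.gene_ids if g in set(counts.gene_ids)]
    if not common:
        raise ValueError("no genes shared between profile and count matrix")
    n_lost = len(profile.gene_ids) - len(common)
    if n_lost:
        logger.info("run_base: %d profile genes absent from count matrix (dropped)", n_lost)
    prof_idx = {g: i for i, g in enumerate(profile.gene_ids)}
    cnt_idx = {g: i for i, g in enumerate(counts.gene_ids)}
    prows = np.array([prof_idx[g] for g in common])
    crows = np.array([cnt_idx[g] for g in common])

    results: list[BaseResult] = []
    for m_idx, motif_id in enumerate(counts.motif_ids):
        b_full = counts.counts[crows, m_idx].astype(float)
        factor = (motif_factors or {}).get(motif_id, motif_id)
        for dir_idx, direction in enumerate(("up", "down")):
            d_dir = profile.direction(direction)[prows]
            flags: list[str] = []
            b = b_full
            if rank_based:
                d_dir = _rank_weights(d_dir)
                b = _rank_weights(b_full)
            if np.ptp(b) == 0:
                flags.append("constant-weights")
            ss = np.random.SeedSequence(
                entropy=seed, spawn_key=(_motif_key(motif_id), dir_idx)
            )
            try:
                res = permutation_pvalue(
                    d_dir, b, K=K, seed=ss, exact=exact, add_one=add_one
                )
                delta, p = res.delta, res.p_value
                n_perm = res.null_scores.size
            except DegenerateDirectionError as err:
                flags.append(
                    "no-differentiation" if "differentiation" in str(err) else "zero-weight"
                )
                delta, p, n_perm = 0.0, 1.0, 0
            results.append(
                BaseResult(
                    motif_id=motif_id,
                    factor_name=factor,
                    direction=direction,
                    delta=delta,
                    p_value=p,
                    q_value=p,  # replaced below
                    n_permutations=n_perm,
                    n_genes=len(common),
                    flags=tuple(flags),
                )
            )

    # FDR within each direction's family, then rank by p within direction
    out: list[BaseResult] = []
    for direction in ("up", "down"):
        fam = [r for r in results if r.direction == direction]
        q = adjust_fdr(np.array([r.p_value for r in fam]), method=fdr)
        for r, qv in zip(fam, q):
            r.q_value = float(qv)
        out.extend(sorted(fam, key=lambda r: (r.p_value, r.motif_id)))
    return out


def adjust_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """FDR adjustment: Benjamini-Hochberg step-up, or Storey q-values.

    Storey uses the lambda = 0.5 plug-in estimate of the null proportion,
    pi0 = min(1, #{p > 0.5} / (0.5 N)), and floors the q-value at the raw p
    so that adjustment never overstates significance.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
        q = pi0 * multipletests(p, method="fdr_bh")[1]
        return np.maximum(q, p)
    raise ValueError(f"unknown FDR method {method!r}")


def results_to_frame(results: Sequence[BaseResult]):
    """Tabulate results: motif_id, factor_name, direction, delta, p, q, ..."""
    import pandas as pd

    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in results],
            "factor_name": [r.factor_name for r in results],
            "direction": [r.direction for r in results],
            "delta": [r.delta for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "n_genes": [r.n_genes for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )
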