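"""Single-sample gene-set scoring (GSVA-style) and cohort association
statistics.

The score follows the gene set variation analysis recipe: per gene a
kernel-smoothed cumulative density across samples (Gaussian kernel with
bandwidth s_g/4 for continuous input, a shifted Poisson kernel for counts);
per sample the genes are ranked by that statistic and the ranks symmetrized
about the center; a weighted Kolmogorov-Smirnov random walk down the ranked
list (weight |r|^tau inside the set) yields, in ``max_diff`` mode, the sum
of the maximum positive and minimum negative deviations, bounded in [-1, 1].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSet

log = logging.getLogger("xenostroma")


# ---------------------------------------------------------------------------
# kernel CDF statistics
# ---------------------------------------------------------------------------

def _gaussian_kcdf(x: np.ndarray) -> np.ndarray:
    """Row-wise kernel CDF: z_ij = mean_k Phi((x_ij - x_ik) / h_i), h = s/4."""
    n = x.shape[1]
    sd = x.std(axis=1, ddof=1, keepdims=True)
    h = np.where(sd > 0, sd / 4.0, 1e-6)
    diff = (x[:, :, None] - x[:, None, :]) / h[:, :, None]
    return stats.norm.cdf(diff).mean(axis=2)


def _poisson_kcdf(x: np.ndarray) -> np.ndarray:
    """Row-wise Poisson kernel CDF for count input, rate x_ik + 0.5."""
    lam = x[:, None, :] + 0.5
    return stats.poisson.cdf(x[:, :, None], lam).mean(axis=2)


def gsva_scores(expr: pd.DataFrame, genesets: dict[str, list[str]] | list[GeneSet],
                kernel: str = "gaussian", tau: float = 1.0,
                mode: str = "max_diff") -> pd.DataFrame:
    """GSVA-style enrichment scores, gene sets x samples.

    Sets with no gene in ``expr`` are dropped with a warning.  Scores are
    invariant under per-gene monotone transforms (the core is rank-based)
    and bounded in [-1, 1].
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if mode != "max_diff":
        raise ValueError("only max_diff scoring is supported")
    if isinstance(genesets, list):
        genesets = {gs.name: gs.members for gs in genesets}

    x = expr.to_numpy(dtype=float)
    p, n = x.shape
    kcdf = {"gaussian": _gaussian_kcdf, "poisson": _poisson_kcdf}[kernel](x)

    # per sample: rank genes by the CDF statistic (1 = highest), then
    # symmetrize the ranks about the center of the list
    order = np.argsort(-kcdf, axis=0, kind="stable")       # gene order, high first
    rank = np.empty_like(order)
    rows = np.arange(p)
    for j in range(n):
        rank[order[:, j], j] = rows + 1
    sym = np.abs(p / 2.0 - rank)                            # |p/2 - rank|

    gene_idx = {g: i for i, g in enumerate(expr.index)}
    out = {}
    for name, members in genesets.items():
        idx = [gene_idx[g] for g in members if g in gene_idx]
        if not idx:
            log.warning("gene set %s has no gene in the expression matrix; dropped", name)
            continue
        inset = np.zeros(p, dtype=bool)
        inset[idx] = True
        scores = np.empty(n)
        for j in range(n):
            walk_order = order[:, j]
            in_walk = inset[walk_order]
            w = sym[walk_order, j] ** tau
            w_in = np.where(in_walk, w, 0.0)
            denom_in = w_in.sum()
            inc_in = np.cumsum(w_in) / denom_in if denom_in > 0 else np.zeros(p)
            inc_out = np.cumsum(~in_walk) / (p - in_walk.sum())
            dev = inc_in - inc_out
            scores[j] = max(dev.max(), 0.0) + min(dev.min(), 0.0)
        out[name] = scores
    return pd.DataFrame(out, index=expr.columns).T


def upper_quartile_normalize(counts: pd.DataFrame, target: float = 1000.0) -> pd.DataFrame:
    """Scale each sample so its upper-quartile nonzero count equals ``target``."""
    out = {}
    for col in counts.columns:
        v = counts[col]
        pos = v[v > 0]
        uq = float(np.quantile(pos, 0.75)) if len(pos) else 1.0
        out[col] = v / uq * target
    return pd.DataFrame(out, index=counts.index)


# ---------------------------------------------------------------------------
# cohort association statistics
# ---------------------------------------------------------------------------

def correlate_gleason(scores: pd.Series, gleason: pd.Series) -> tuple[float, float]:
    """Spearman correlation of signature scores with Gleason grade."""
    paired = pd.concat([scores, gleason], axis=1).dropna()
    if len(paired) < 4:
        raise ValueError("need at least 4 paired observations")
    a, b = paired.iloc[:, 0], paired.iloc[:, 1]
    if a.nunique() == 1 or b.nunique() == 1:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def compare_sample_types(scores: pd.Series, types: pd.Series,
                         group_a: str = "TP", group_b: str = "NT") -> tuple[float, float]:
    """Two-sided Mann-Whitney U for signature scores between sample types.

    Exact enumeration when both groups have at most 8 observations,
    otherwise the tie-corrected normal approximation.
    """
    a = scores[types == group_a].dropna()
    b = scores[types == group_b].dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and
                         not np.intersect1d(a, b).size) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def stratify_quartiles(scores: pd.Series) -> pd.Series:
    """Rank-based Q1 / Q2-3 / Q4 labels at the 25th and 75th percentiles.

    Ties are broken by stable sample order so group sizes stay within one of
    n/4, n/2, n/4.  All-tied scores collapse to a single middle group, which
    is flagged rather than raising.
    """
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if scores.nunique() == 1:
        log.warning("all scores tied: single stratum")
        return pd.Series(["Q2_3"] * n, index=scores.index, name="stratum")
    order = np.argsort(scores.to_numpy(), kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    lo, hi = round(n / 4), n - round(n / 4)
    labels = np.where(rank < lo, "Q1", np.where(rank >= hi, "Q4", "Q2_3"))
    return pd.Series(labels, index=scores.index, name="stratum")
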