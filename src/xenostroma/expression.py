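"""Expression summaries and differential expression for count matrices.

Covers CPM/TPM/FPKM transforms with the study's pseudo-count and filtering
conventions, zFPKM expressed-gene calls, top-variable-gene PCA, TMM
(weighted trimmed mean of M-values) normalization factors, and a negative
binomial quasi-likelihood F test:

* per gene a one-way NB log-linear model with effective-library-size
  offsets is fitted by Newton scoring;
* a common dispersion maximizes the Cox-Reid adjusted profile likelihood on
  a grid, gene-wise dispersions are shrunk toward it with weight
  proportional to residual degrees of freedom (prior df 10);
* a quasi-dispersion from deviance residuals is moderated the same way and
  scales the squared contrast t statistic into an F statistic with
  ``residual df + prior df`` denominator degrees of freedom;
* genes pass the significance filter at strict FDR < 0.05 and strict
  fold change > 2 (|log2FC| > 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

log = logging.getLogger("xenostroma")


def _counts_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


# ---------------------------------------------------------------------------
# unit transforms
# ---------------------------------------------------------------------------

def cpm(counts, factors: "NormalizationFactors | None" = None) -> pd.DataFrame:
    """Counts per million; per-sample columns sum to 1e6.

    With ``factors`` the effective (TMM-scaled) library sizes are used, in
    which case columns sum to 1e6 / factor instead.
    """
    c = _counts_frame(counts)
    lib = c.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    if factors is not None:
        lib = factors.effective_lib_sizes(c).loc[c.columns]
    return c / lib * 1e6


def cpm_log2(counts, factors: "NormalizationFactors | None" = None) -> pd.DataFrame:
    """log2(CPM + 1); the pseudo-count keeps zeros at 0."""
    return np.log2(cpm(counts, factors) + 1.0)


def filter_low(counts: CountMatrix, cpm_log2_threshold: float = 1.0,
               max_low_samples: int = 3) -> CountMatrix:
    """Remove genes low in more than ``max_low_samples`` samples.

    A gene is retained iff the number of samples with log2(CPM+1) below the
    threshold is at most ``max_low_samples`` (strictly "more than" removes).
    """
    if cpm_log2_threshold < 0 or max_low_samples < 0:
        raise ValueError("thresholds must be non-negative")
    lc = cpm_log2(counts)
    keep = (lc < cpm_log2_threshold).sum(axis=1) <= max_low_samples
    log.info("filter_low: %d of %d genes retained", int(keep.sum()), len(keep))
    return CountMatrix(counts.counts[keep], counts.meta, counts.species)


def tpm(counts, lengths: dict[str, float] | pd.Series) -> pd.DataFrame:
    """Transcripts per million from counts and transcript lengths."""
    c = _counts_frame(counts)
    lengths = pd.Series(lengths)
    missing = c.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing transcript length for {list(missing[:3])}")
    ln = lengths.loc[c.index]
    if (ln <= 0).any():
        raise ValueError("transcript lengths must be positive")
    rate = c.div(ln, axis=0)
    return rate / rate.sum(axis=0) * 1e6


def fpkm(counts, lengths: dict[str, float] | pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads."""
    c = _counts_frame(counts)
    ln = pd.Series(lengths).loc[c.index]
    return cpm(c).div(ln / 1e3, axis=0)


# ---------------------------------------------------------------------------
# zFPKM
# ---------------------------------------------------------------------------

def zfpkm(fpkm_matrix: pd.DataFrame, grid_size: int = 512) -> pd.DataFrame:
    """Mode-anchored z-transform of log2 FPKM, per sample.

    The location is the mode of a Gaussian kernel density (Silverman
    bandwidth) over the log2 FPKM of nonzero genes; the scale is the mean
    exceedance above the mode times sqrt(pi/2), i.e. the standard deviation
    of the right half-normal.  Zero-FPKM genes map to -inf.
    """
    if (fpkm_matrix.values < 0).any():
        raise ValueError("FPKM must be non-negative")
    out = {}
    for col in fpkm_matrix.columns:
        v = fpkm_matrix[col].to_numpy(dtype=float)
        pos = v > 0
        if pos.sum() < 10:
            raise ValueError(f"sample {col}: fewer than 10 nonzero genes")
        x = np.log2(v[pos])
        kde = stats.gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(x.min(), x.max(), grid_size)
        mu = float(grid[np.argmax(kde(grid))])
        upper = x[x > mu]
        if len(upper) == 0:
            raise ValueError(f"sample {col}: no mass above the density mode")
        sigma = float((upper - mu).mean()) * np.sqrt(np.pi / 2.0)
        z = np.full_like(v, -np.inf)
        z[pos] = (x - mu) / sigma
        out[col] = z
    return pd.DataFrame(out, index=fpkm_matrix.index)


def expressed_calls(z: pd.DataFrame, threshold: float = -3.0) -> list[str]:
    """Genes with zFPKM strictly above the threshold in all samples."""
    return list(z.index[(z > threshold).all(axis=1)])


# ---------------------------------------------------------------------------
# variable genes and PCA
# ---------------------------------------------------------------------------

def top_variable(log_expr: pd.DataFrame, n: int = 500) -> list[str]:
    """The n genes with highest across-sample variance, ties by gene id."""
    if n > len(log_expr):
        raise ValueError("n exceeds number of genes")
    var = log_expr.var(axis=1, ddof=1)
    order = sorted(log_expr.index, key=lambda g: (-var[g], g))
    return order[:n]


def pca(log_expr: pd.DataFrame, n_components: int = 2, scale: bool = False) -> pd.DataFrame:
    """Sample coordinates from an SVD of gene-centered expression."""
    n_samples = log_expr.shape[1]
    if n_components > n_samples - 1:
        raise ValueError("n_components must be at most samples - 1")
    x = log_expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    if scale:
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    return pd.DataFrame(coords, index=log_expr.columns,
                        columns=[f"PC{i + 1}" for i in range(n_components)])


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationFactors:
    factors: pd.Series       # unit geometric mean
    ref_sample: str

    def effective_lib_sizes(self, counts) -> pd.Series:
        c = _counts_frame(counts)
        return c.sum(axis=0) * self.factors


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    ok = (obs > 0) & (ref > 0)
    if ok.sum() == 0:
        return 1.0
    y, r = obs[ok], ref[ok]
    m = np.log2((y / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((y / n_obs) * (r / n_ref))
    w = (n_obs - y) / (n_obs * y) + (n_ref - r) / (n_ref * r)
    if np.abs(m).max() < 1e-6:  # identical proportions: no trimming needed
        return 1.0
    n = len(m)
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if keep.sum() == 0 or w[keep].sum() == 0:
        return 1.0
    return float(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def tmm_factors(counts, trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizationFactors:
    """Weighted trimmed mean of M-values normalization factors.

    The reference sample is the one whose upper-quartile count proportion is
    closest to the mean upper quartile.  Per sample, M-values against the
    reference are trimmed (30% of M from each tail, 5% of A) and averaged
    with inverse asymptotic-variance weights; factors are rescaled to unit
    geometric mean.
    """
    c = _counts_frame(counts)
    if c.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = c.sum(axis=0).to_numpy(dtype=float)
    x = c.to_numpy(dtype=float)
    q75 = np.array([np.quantile(x[:, j][x[:, j] > 0] / lib[j], 0.75)
                    if (x[:, j] > 0).any() else 0.0 for j in range(x.shape[1])])
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_j:
            continue
        if not ((x[:, j] > 0) & (x[:, ref_j] > 0)).any():
            log.warning("sample %s shares no expressed genes with the reference; factor 1",
                        c.columns[j])
            continue
        f[j] = _tmm_pair(x[:, j], x[:, ref_j], lib[j], lib[ref_j], trim_m, trim_a)
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationFactors(pd.Series(f, index=c.columns, name="tmm_factor"),
                                str(c.columns[ref_j]))


# ---------------------------------------------------------------------------
# NB quasi-likelihood test
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    table: pd.DataFrame      # log2FC, logCPM, F, p, FDR, dispersion
    contrast: tuple[str, str]
    excluded: list[str]      # all-zero genes

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def _fit_groups(y: np.ndarray, off: np.ndarray, groups: np.ndarray,
                phi: np.ndarray, n_iter: int = 25) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene NB group means via Newton scoring on the log scale.

    Returns (beta, info, mu): beta and Fisher information per (gene, group),
    mu per (gene, sample).  ``phi`` is per-gene.
    """
    n_genes, n_samp = y.shape
    labels = np.unique(groups)
    beta = np.zeros((n_genes, len(labels)))
    info = np.zeros((n_genes, len(labels)))
    mu = np.zeros_like(y, dtype=float)
    for gi, g in enumerate(labels):
        cols = np.nonzero(groups == g)[0]
        yg = y[:, cols]
        og = off[cols]
        b = np.log((yg.sum(axis=1) + 0.125) / np.exp(og).sum())
        ph = phi[:, None]
        for _ in range(n_iter):
            m = np.exp(og[None, :] + b[:, None])
            denom = 1.0 + ph * m
            score = ((yg - m) / denom).sum(axis=1)
            inf = (m / denom).sum(axis=1)
            step = score / np.maximum(inf, 1e-12)
            step = np.clip(step, -5.0, 5.0)
            b = b + step
            if np.abs(step).max() < 1e-10:
                break
        m = np.exp(og[None, :] + b[:, None])
        beta[:, gi] = b
        info[:, gi] = (m / (1.0 + ph * m)).sum(axis=1)
        mu[:, cols] = m
    return beta, info, mu


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log likelihood (phi > 0) or Poisson limit (phi == 0)."""
    out = np.zeros(y.shape[0])
    pos = phi > 0
    if pos.any():
        r = 1.0 / phi[pos, None]
        m = mu[pos]
        yy = y[pos]
        out[pos] = (special.gammaln(yy + r) - special.gammaln(r) - special.gammaln(yy + 1)
                    + yy * np.log(m / (m + r)) + r * np.log(r / (r + m))).sum(axis=1)
    if (~pos).any():
        m = np.maximum(mu[~pos], 1e-300)
        yy = y[~pos]
        out[~pos] = (yy * np.log(m) - m - special.gammaln(yy + 1)).sum(axis=1)
    return out


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB deviance (2 * [loglik(saturated) - loglik(fit)])."""
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        ph = phi[:, None]
        pos = ph > 0
        t2 = np.where(pos,
                      (y + 1.0 / np.where(pos, ph, 1.0))
                      * np.log((1.0 + ph * mu) / (1.0 + ph * y)),
                      mu - y)
    return 2.0 * (t1 + t2).sum(axis=1)


def _interp_max(grid: np.ndarray, values: np.ndarray) -> float:
    """Quadratic interpolation of the maximizer on a log-spaced grid."""
    k = int(np.argmax(values))
    if k == 0 or k == len(grid) - 1:
        return float(grid[k])
    x = np.log(grid[k - 1:k + 2])
    v = values[k - 1:k + 2]
    curv = v[0] - 2 * v[1] + v[2]
    if curv >= 0:
        return float(grid[k])
    return float(np.exp(x[1] - 0.5 * (x[2] - x[0]) / 2 * (v[2] - v[0]) / curv))


def nb_ql_test(counts, factors: NormalizationFactors, groups: pd.Series,
               contrast: tuple[str, str], prior_df: float = 10.0,
               grid: np.ndarray | None = None) -> DEResult:
    """NB quasi-likelihood F test of ``contrast = (test, reference)``.

    ``groups`` maps sample id to group label; log2FC is test minus reference.
    All-zero genes are excluded with a flag.
    """
    c = _counts_frame(counts)
    groups = groups.loc[c.columns]
    used = groups.isin(contrast)
    if used.sum() < 4 or groups[used].nunique() < 2:
        raise ValueError("contrast needs two groups with at least 2 samples each")
    test_g, ref_g = contrast

    nonzero = c.sum(axis=1) > 0
    excluded = list(c.index[~nonzero])
    if excluded:
        log.info("nb_ql_test: excluding %d all-zero genes", len(excluded))
    c = c[nonzero]
    y = c.to_numpy(dtype=float)
    eff = factors.effective_lib_sizes(c).loc[c.columns].to_numpy(dtype=float)
    off = np.log(eff)
    grp = groups.to_numpy()
    n_genes, n_samp = y.shape
    df_resid = n_samp - len(np.unique(grp))
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    # dispersion: adjusted profile likelihood on a grid
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-4), np.log(4.0), 40))
    apl = np.zeros((n_genes, len(grid)))
    for k, phi in enumerate(grid):
        ph = np.full(n_genes, phi)
        beta, info, mu = _fit_groups(y, off, grp, ph)
        cr = 0.5 * np.log(np.maximum(info, 1e-12)).sum(axis=1)
        apl[:, k] = _nb_loglik(y, mu, ph) - cr
    common_phi = _interp_max(grid, apl.sum(axis=0))
    gene_phi = np.array([_interp_max(grid, apl[i]) for i in range(n_genes)])
    w = df_resid / (df_resid + prior_df)
    mod_phi = np.exp(w * np.log(gene_phi) + (1 - w) * np.log(common_phi))

    beta, info, mu = _fit_groups(y, off, grp, mod_phi)
    labels = list(np.unique(grp))
    ti, ri = labels.index(test_g), labels.index(ref_g)
    lfc = (beta[:, ti] - beta[:, ri]) / np.log(2.0)
    var_beta = 1.0 / np.maximum(info[:, ti], 1e-12) + 1.0 / np.maximum(info[:, ri], 1e-12)

    # quasi-dispersion from deviance residuals, moderated toward the mean
    dev = _nb_deviance(y, mu, mod_phi)
    s2 = dev / df_resid
    s2_0 = float(np.mean(s2))
    s2_mod = (prior_df * s2_0 + df_resid * s2) / (prior_df + df_resid)
    df_total = df_resid + prior_df

    fstat = (beta[:, ti] - beta[:, ri]) ** 2 / (var_beta * s2_mod)
    p = stats.f.sf(fstat, 1, df_total)
    fdr = multipletests(p, method="fdr_bh")[1]
    log_cpm = np.log2(np.maximum(mu.mean(axis=1) / eff.mean(), 1e-9) * 1e6 + 1.0)
    table = pd.DataFrame({"log2FC": lfc, "logCPM": log_cpm, "F": fstat,
                          "p": p, "FDR": fdr, "dispersion": mod_phi},
                         index=c.index)
    return DEResult(table, contrast, excluded)


def significant(de: DEResult, fdr: float = 0.05, fold: float = 2.0) -> list[str]:
    """Genes at strict FDR < ``fdr`` and strict fold change > ``fold``."""
    t = de.table
    keep = (t["FDR"] < fdr) & (t["log2FC"].abs() > np.log2(fold))
    return list(t.index[keep])


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

def zscore_matrix(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z across samples with n-1 sd; constant genes get zero rows."""
    if log_expr.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    mean = log_expr.mean(axis=1)
    sd = log_expr.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        log.info("zscore_matrix: %d constant gene(s) set to zero rows", int(flat.sum()))
    z = log_expr.sub(mean, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    return z
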