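"""Count-matrix normalization and negative-binomial differential modelling.

The model is the standard paired-design translatome regression: for gene g
and sample j with normalized mean mu_gj,

    log mu_gj = log s_j + x_j' beta_g,      Var(Y_gj) = mu_gj + alpha_g mu_gj^2

with RLE (median-of-ratios) size factors s_j as offsets, fixed pair effects
nested in condition, a fraction main effect (IP vs total), condition main
effects and fraction x condition interactions.  The interaction coefficient
at an injury timepoint is the differential-enrichment statistic
delta Log2FC(IP/total) = Log2FC(IP/total)_injury - Log2FC(IP/total)_baseline.
Gene-level screening uses a full-versus-reduced likelihood ratio test (the
reduced model drops all interactions); per-timepoint effects use Wald tests.

All coefficients are reported in log2 units.  Fitting is a per-gene IRLS
run vectorized across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

IP_FRACTION = "OL"
TOTAL_FRACTION = "total"

DISPERSION_FLOOR = 1e-8
IRLS_MAX_ITER = 100
IRLS_TOL = 1e-8
LN2 = np.log(2.0)


class DesignError(ValueError):
    """Raised for rank-deficient or non-nested design problems."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus per-sample metadata.

    ``samples`` must have columns sample_id, fraction (``OL``/``total``),
    condition and pair_id; ``conditions`` fixes the condition order with
    the baseline first.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    conditions: List[str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            self.samples = (self.samples.set_index("sample_id")
                            .loc[list(self.counts.columns)].reset_index())
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        unknown = set(self.samples["condition"]) - set(self.conditions)
        if unknown:
            raise ValueError(f"conditions {sorted(unknown)} not in declared order")
        ip = self.samples[self.samples["fraction"] == IP_FRACTION]
        tot = self.samples[self.samples["fraction"] == TOTAL_FRACTION]
        tot_pairs = tot.groupby("pair_id")["condition"].first()
        for _, row in ip.iterrows():
            if tot_pairs.get(row["pair_id"]) != row["condition"]:
                raise ValueError(
                    f"IP sample {row['sample_id']} has no matching total sample "
                    f"in pair {row['pair_id']}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def baseline(self) -> str:
        return self.conditions[0]

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.samples.copy(),
                           list(self.conditions))


@dataclass
class SizeFactors:
    factors: pd.Series          # per sample, positive, geometric mean 1
    reference: pd.Series        # per-gene geometric means over reference genes

    def log_offsets(self) -> np.ndarray:
        return np.log(self.factors.to_numpy())


def filter_low_counts(cm: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes with fewer than ``min_total`` summed counts across all
    samples (the DESeq2-style pre-filter); order preserved."""
    keep = cm.counts.sum(axis=1) >= min_total
    if not keep.any():
        warnings.warn("count filter removed every gene", stacklevel=2)
    return CountMatrix(cm.counts.loc[keep], cm.samples.copy(),
                       list(cm.conditions))


def estimate_size_factors(cm: CountMatrix) -> SizeFactors:
    """RLE / median-of-ratios size factors.

    Reference genes are those with no zero count; s_j is the median across
    reference genes of count_gj over the gene's geometric mean, rescaled so
    the factors have geometric mean 1.
    """
    counts = cm.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has all-positive counts; RLE needs at least one "
            "zero-free reference gene (consider a pseudo-reference fallback)")
    ref = counts[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.exp(np.log(ref) - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    genes = cm.gene_ids[positive]
    return SizeFactors(
        factors=pd.Series(s, index=cm.counts.columns, name="size_factor"),
        reference=pd.Series(np.exp(log_geomean), index=genes, name="geomean"))


def estimate_dispersions(cm: CountMatrix, sf: SizeFactors,
                         floor: float = DISPERSION_FLOOR,
                         moderate: bool = True) -> pd.Series:
    """Per-gene NB dispersion on normalized counts, with empirical-Bayes
    trend moderation.

    Within each fraction x condition design cell the moment identity
    Var = mu + alpha mu^2 gives the gene-wise estimate
    (var - mean) / mean^2, pooled across cells by a ratio of sums weighted
    with residual degrees of freedom.  With ``moderate=True`` (default)
    gene-wise values are then shrunk in log space toward a fitted
    mean-dispersion trend a0 + a1/mu, weighting by the sampling variance
    of a log dispersion estimate at the design's residual df versus the
    estimated prior spread of true dispersions around the trend — the
    standard stabilization for designs with few replicates per cell, where
    raw moment estimates are too noisy for calibrated Wald inference.
    """
    if cm.samples.shape[0] < 3:
        raise ValueError("dispersion estimation needs at least 3 samples")
    norm = cm.counts.to_numpy(dtype=float) / sf.factors.to_numpy()[None, :]
    cells = cm.samples.groupby(["fraction", "condition"], sort=True,
                               observed=True).indices
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    resid_df = 0
    for idx in cells.values():
        cols = np.asarray(idx)
        if len(cols) < 2:
            continue
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(cols) - 1
        resid_df += w
        num += w * (v - m)
        den += w * m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, floor)
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    alpha = np.maximum(alpha, floor)
    out = pd.Series(alpha, index=cm.gene_ids, name="alpha")
    if moderate and resid_df >= 2:
        base_mean = norm.mean(axis=1)
        moderated, prior_var = _moderate_dispersions(alpha, base_mean,
                                                     resid_df, floor)
        out = pd.Series(moderated, index=cm.gene_ids, name="alpha")
        # Wald/LRT reference df: dispersion information from the residual
        # df plus what the trend prior contributes (moderated-t logic).
        out.attrs["resid_df"] = resid_df
        out.attrs["prior_df"] = _prior_df(prior_var)
        out.attrs["t_df"] = resid_df + out.attrs["prior_df"]
    return out


def _dispersion_trend(alpha_gw: np.ndarray, base_mean: np.ndarray
                      ) -> np.ndarray:
    """Fit the parametric trend alpha(mu) = a0 + a1/mu by trimmed least
    squares on informative gene-wise estimates; falls back to the median
    when the regression degenerates."""
    usable = (alpha_gw > 1e-6) & (base_mean > 0)
    if usable.sum() < 50:
        return np.full_like(alpha_gw, max(np.median(alpha_gw), 1e-6))
    x = 1.0 / base_mean[usable]
    y = alpha_gw[usable]
    a0, a1 = max(np.median(y), 1e-6), 0.0
    for _ in range(3):
        fitted = a0 + a1 * x
        keep = (y > fitted / 100.0) & (y < fitted * 15.0)
        if keep.sum() < 50:
            break
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        coef, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        a0 = max(coef[0], 1e-8)
        a1 = max(coef[1], 0.0)
    trend = a0 + a1 / np.maximum(base_mean, 1e-8)
    return np.maximum(trend, 1e-8)


def _moderate_dispersions(alpha_gw: np.ndarray, base_mean: np.ndarray,
                          resid_df: int, floor: float) -> np.ndarray:
    """Log-space shrinkage of gene-wise dispersions toward the trend.

    The sampling variance of a log dispersion estimate at d residual df is
    approximately trigamma(d/2); the prior variance is the robust spread
    of log gene-wise estimates around the log trend minus that sampling
    noise (floored at 0.25, as in standard practice).  Genes far above the
    trend (dispersion outliers) keep their gene-wise value.
    """
    trend = _dispersion_trend(alpha_gw, base_mean)
    log_gw = np.log(np.maximum(alpha_gw, 1e-8))
    log_tr = np.log(trend)
    s_lr2 = float(special.polygamma(1, resid_df / 2.0))
    resid = (log_gw - log_tr)[alpha_gw > 1e-6]
    if resid.size >= 50:
        mad = np.median(np.abs(resid - np.median(resid)))
        prior_var = max((1.4826 * mad) ** 2 - s_lr2, 0.25)
    else:
        prior_var = 0.25
    w = prior_var / (prior_var + s_lr2)
    log_post = w * log_gw + (1.0 - w) * log_tr
    out = np.exp(log_post)
    outlier = log_gw > log_tr + 2.0 * np.sqrt(s_lr2 + prior_var)
    out[outlier] = alpha_gw[outlier]
    return np.maximum(out, floor), prior_var


def _prior_df(prior_var: float) -> float:
    """Degrees of freedom whose log-variance sampling noise trigamma(d/2)
    equals the prior variance — the information the trend contributes."""
    from scipy.optimize import brentq

    f = lambda d: special.polygamma(1, d / 2.0) - prior_var
    return float(brentq(f, 1e-3, 1e8))


# ---------------------------------------------------------------------------
# Design matrices


@dataclass
class Design:
    """Design matrix with named columns for the paired two-fraction layout."""

    matrix: np.ndarray
    columns: List[str]
    interaction: bool

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


def build_design(samples: pd.DataFrame, conditions: Sequence[str],
                 interaction: bool = True, pair_term: bool = True) -> Design:
    """Build {intercept, pair-within-condition, condition, fraction,
    fraction:condition} columns.

    Pair columns aliased with condition (the first pair of each condition,
    in input order) are dropped deterministically.
    """
    n = samples.shape[0]
    cols: Dict[str, np.ndarray] = {"intercept": np.ones(n)}
    baseline = conditions[0]
    cond = samples["condition"].to_numpy()
    frac = (samples["fraction"] == IP_FRACTION).to_numpy(dtype=float)
    if pair_term:
        for c in conditions:
            pairs = list(dict.fromkeys(
                samples.loc[cond == c, "pair_id"]))
            for p in pairs[1:]:
                cols[f"pair[{p}]"] = (samples["pair_id"] == p).to_numpy(float)
    for c in conditions:
        if c == baseline:
            continue
        cols[f"condition[{c}]"] = (cond == c).astype(float)
    cols["fraction[OL]"] = frac
    if interaction:
        for c in conditions:
            if c == baseline:
                continue
            cols[f"fraction[OL]:condition[{c}]"] = frac * (cond == c)
    X = np.column_stack(list(cols.values()))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by greedy QR-style elimination
        keep, aliased = [], []
        for i, name in enumerate(cols):
            trial = X[:, keep + [i]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(i)
            else:
                aliased.append(name)
        raise DesignError(f"design matrix rank deficient; aliased columns: "
                          f"{aliased}")
    return Design(matrix=X, columns=list(cols), interaction=interaction)


# ---------------------------------------------------------------------------
# NB GLM via vectorized IRLS


@dataclass
class ModelFit:
    """Per-gene NB GLM fits (coefficients in log2 units)."""

    design: Design
    coef: pd.DataFrame            # genes x columns, log2
    cov: np.ndarray               # genes x p x p, log2^2
    llf: pd.Series                # per-gene log-likelihood (natural log)
    alpha: pd.Series
    converged: pd.Series
    base_mean: pd.Series          # mean normalized count
    t_df: float | None = None     # Wald reference df (None = normal)

    @property
    def gene_ids(self) -> pd.Index:
        return self.coef.index


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; alpha at the floor behaves as Poisson."""
    a = np.maximum(alpha, DISPERSION_FLOOR)[:, None]
    r = 1.0 / a
    mu = np.maximum(mu, 1e-12)
    ll = (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
          + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    return ll.sum(axis=1)


def fit_nb_glm(cm: CountMatrix, sf: SizeFactors, alpha: pd.Series,
               design: Design) -> ModelFit:
    """Fit the NB log-linear model per gene by IRLS, all genes in parallel.

    Log size factors enter as offsets.  Non-converged genes are flagged,
    not dropped.  The coefficient covariance comes from the observed
    (expected, for the log link) information matrix.
    """
    Y = cm.counts.to_numpy(dtype=float)
    G, n = Y.shape
    X = design.matrix
    p = X.shape[1]
    offset = sf.log_offsets()[None, :]
    a = np.maximum(alpha.loc[cm.gene_ids].to_numpy(), DISPERSION_FLOOR)[:, None]

    beta = np.zeros((G, p))
    beta[:, design.column_index("intercept")] = np.log(
        np.maximum(Y.mean(axis=1), 0.1))
    eye = np.eye(p)[None, :, :]
    dev_old = np.full(G, np.inf)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)

    for _ in range(IRLS_MAX_ITER):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = beta[idx] @ X.T + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a[idx] * mu)
        z = (eta - offset) + (Y[idx] - mu) / mu
        xtwx = np.einsum("ji,gj,jk->gik", X, w, X)
        xtwz = np.einsum("ji,gj->gi", X, w * z)
        try:
            beta_new = np.linalg.solve(xtwx + 1e-10 * eye, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(
                xtwx.reshape(-1, p, p)[0], xtwz[0], rcond=None)[0][None, :]
        bad = ~np.isfinite(beta_new).all(axis=1)
        beta_new[bad] = beta[idx][bad]
        beta[idx] = beta_new

        eta = np.clip(beta[idx] @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        dev = -2.0 * _nb_loglik(Y[idx], mu, a[idx, 0])
        delta = np.abs(dev - dev_old[idx]) / (np.abs(dev) + 0.1)
        done = delta < IRLS_TOL
        converged[idx[done]] = True
        dev_old[idx] = dev
        active[idx[done]] = False

    eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + a * mu)
    info = np.einsum("ji,gj,jk->gik", X, w, X)
    cov = np.linalg.pinv(info + 1e-10 * eye)
    llf = _nb_loglik(Y, mu, a[:, 0])

    base_mean = (Y / sf.factors.to_numpy()[None, :]).mean(axis=1)
    coef = pd.DataFrame(beta / LN2, index=cm.gene_ids, columns=design.columns)
    return ModelFit(design=design, coef=coef, cov=cov / LN2 ** 2,
                    llf=pd.Series(llf, index=cm.gene_ids, name="llf"),
                    alpha=pd.Series(a[:, 0], index=cm.gene_ids, name="alpha"),
                    converged=pd.Series(converged, index=cm.gene_ids,
                                        name="converged"),
                    base_mean=pd.Series(base_mean, index=cm.gene_ids,
                                        name="baseMean"),
                    t_df=alpha.attrs.get("t_df"))


def contrast_vector(design: Design, terms: Dict[str, float]) -> np.ndarray:
    """Build a contrast c from {column name: weight}."""
    c = np.zeros(len(design.columns))
    for name, w in terms.items():
        c[design.column_index(name)] = w
    return c


def wald_contrast(fit: ModelFit, contrast: np.ndarray,
                  adjust: bool = True) -> pd.DataFrame:
    """Wald test of c'beta = 0 with a two-sided normal p.

    Returns a ContrastResult table (gene_id index; baseMean, log2fc, se,
    stat, pvalue, qvalue, test_kind).  Non-converged genes get missing
    p-values and are excluded from the BH adjustment.
    """
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (len(fit.design.columns),):
        raise DesignError("contrast dimension does not match design")
    if not np.any(contrast):
        raise DesignError("degenerate all-zero contrast")
    lfc = fit.coef.to_numpy() @ contrast
    var = np.einsum("i,gij,j->g", contrast, fit.cov, contrast)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / se, np.nan)
    # Student-t reference when the dispersion carries finite df; normal in
    # the well-replicated limit (moderated-t logic).
    if fit.t_df is not None and np.isfinite(fit.t_df):
        pvalue = 2.0 * stats.t.sf(np.abs(stat), fit.t_df)
    else:
        pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.where(fit.converged.to_numpy() & np.isfinite(stat),
                      pvalue, np.nan)
    out = pd.DataFrame({"baseMean": fit.base_mean, "log2fc": lfc, "se": se,
                        "stat": stat, "pvalue": pvalue}, index=fit.gene_ids)
    out["qvalue"] = bh_adjust(out["pvalue"]) if adjust else np.nan
    out["test_kind"] = "wald"
    return out


def lrt_interaction(fit_full: ModelFit, fit_reduced: ModelFit,
                    adjust: bool = True) -> pd.DataFrame:
    """Full-versus-reduced likelihood ratio test (chi-square).

    Designs must be nested with the same genes and shared per-gene
    dispersions; negative statistics are clipped to zero with a warning.
    """
    full_cols = set(fit_full.design.columns)
    red_cols = set(fit_reduced.design.columns)
    df = len(full_cols) - len(red_cols)
    if df <= 0 or not red_cols < full_cols:
        raise DesignError("designs are not strictly nested")
    if not fit_full.gene_ids.equals(fit_reduced.gene_ids):
        raise DesignError("fits cover different genes")
    if not np.allclose(fit_full.alpha, fit_reduced.alpha):
        raise DesignError("fits must share per-gene dispersions")
    stat = 2.0 * (fit_full.llf.to_numpy() - fit_reduced.llf.to_numpy())
    if (stat < -1e-6).any():
        warnings.warn("negative LRT statistics clipped to 0; refit advised",
                      stacklevel=2)
    stat = np.maximum(stat, 0.0)
    if fit_full.t_df is not None and np.isfinite(fit_full.t_df):
        # moderated-F reference; tends to chi2/df as the df grow
        pvalue = stats.f.sf(stat / df, df, fit_full.t_df)
    else:
        pvalue = stats.chi2.sf(stat, df)
    ok = (fit_full.converged & fit_reduced.converged).to_numpy()
    pvalue = np.where(ok, pvalue, np.nan)
    out = pd.DataFrame({"baseMean": fit_full.base_mean,
                        "log2fc": np.nan, "se": np.nan,
                        "stat": stat, "pvalue": pvalue},
                       index=fit_full.gene_ids)
    out["qvalue"] = bh_adjust(out["pvalue"]) if adjust else np.nan
    out["test_kind"] = "lrt"
    return out


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up over non-missing p; missing stays missing."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="qvalue")
    return q


@dataclass
class PcaSummary:
    variance_fraction: pd.Series      # per component
    scores: pd.DataFrame              # samples x components


def pca_variance(cm: CountMatrix, sf: SizeFactors, k: int = 3) -> PcaSummary:
    """PCA of log2(normalized count + 1), gene-centered, samples as
    observations."""
    n = cm.samples.shape[0]
    if k > n:
        warnings.warn(f"k={k} exceeds {n} samples; clipped", stacklevel=2)
        k = n
    mat = np.log2(cm.counts.to_numpy(float) / sf.factors.to_numpy()[None, :]
                  + 1.0).T                      # samples x genes
    pca = PCA(n_components=k, svd_solver="full")   # exact, deterministic
    scores = pca.fit_transform(mat)
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaSummary(
        variance_fraction=pd.Series(pca.explained_variance_ratio_, index=comps),
        scores=pd.DataFrame(scores, index=cm.counts.columns, columns=comps))
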