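"""Negative-binomial Wald differential expression.

The engine mirrors the standard bulk RNA-seq workflow: filter genes with a
low median raw count, estimate median-of-ratios size factors, optionally
estimate latent covariates (surrogates) by residual PCA, fit a per-gene
negative-binomial log-link GLM with a log size-factor offset, and test one
design coefficient with a Wald z statistic, correcting p-values by
Benjamini-Hochberg.

The model object / results object split follows statsmodels:
``NBDifferential(counts, samples, contrast=...).fit()`` returns a
:class:`DEResults` carrying the per-gene table, fit diagnostics and a
``summary()``.

Per-gene dispersions use a method-of-moments estimate on size-factor
normalized counts with design-cell means removed, shrunk 50/50 toward a
least-squares trend alpha(mu) = a0 + a1/mu.  IRLS is vectorised across
genes (one batched linear solve per iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, DataError, ExpressionMatrix, SampleTable

_LN2 = np.log(2.0)

DISPERSION_FLOOR = 1e-8
IRLS_TOL = 1e-8
IRLS_MAXIT = 100


# ---------------------------------------------------------------------------
# filtering / normalization


def filter_low_expressed(counts: CountMatrix, min_median: int = 10) -> CountMatrix:
    """Drop genes whose median raw count across all samples is < min_median.

    The even-n median is the mean of the two central order statistics, so a
    gene at exactly the threshold is kept (the cut is strict ``<``).
    """
    if counts.n_samples < 1:
        raise DataError("count matrix has no samples")
    medians = np.median(counts.counts, axis=1)
    keep = medians >= min_median
    if not keep.any():
        raise DataError(
            f"all {counts.n_genes} genes fall below median count {min_median}; "
            "review the filtering threshold"
        )
    return counts.subset_genes(keep)


def estimate_size_factors(counts: CountMatrix) -> pd.DataFrame:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample: median over all-positive genes of count / geometric mean of
    that gene across samples.
    """
    x = counts.counts.astype(float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise DataError("no gene has strictly positive counts in every sample")
    lx = np.log(x[allpos])
    log_geomean = lx.mean(axis=1, keepdims=True)
    log_ratios = lx - log_geomean
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.DataFrame(
        {"sample_id": counts.sample_ids, "size_factor": np.exp(log_sf)}
    )


def compute_log_cpm(counts: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count / library size * 1e6 + pseudocount)."""
    libsize = counts.counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        j = int(np.argmax(libsize == 0))
        raise DataError(f"sample {counts.sample_ids[j]!r} has zero library size")
    cpm = counts.counts / libsize * 1e6
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), np.log2(cpm + pseudocount)
    )


# ---------------------------------------------------------------------------
# design construction


def design_matrix(meta: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Intercept plus 0/1 indicator columns for the requested terms.

    ``genotype`` codes HET = 1, ``treatment`` codes DRUG = 1.
    """
    cols = [np.ones(len(meta))]
    for t in terms:
        if t == "genotype":
            cols.append((meta["genotype"] == "HET").to_numpy(dtype=float))
        elif t == "treatment":
            cols.append((meta["treatment"] == "DRUG").to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown design term {t!r}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError(f"design with terms {terms} is rank deficient")
    return X


def estimate_surrogates(
    counts: CountMatrix,
    samples: SampleTable,
    design_terms: list[str],
    k: int,
) -> pd.DataFrame:
    """Residual-PCA surrogate covariates.

    Per-gene least squares of log2 CPM on the design; the first ``k``
    sample-space principal components of the residual matrix are returned,
    each centered and unit-norm.  This is a simplified latent-covariate
    estimator: a single pass, no iterated reweighting.
    """
    meta = samples.aligned(counts.sample_ids)
    X = design_matrix(meta, design_terms)
    n, p = X.shape
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return pd.DataFrame({"sample_id": counts.sample_ids})
    if k >= n - p:
        raise DataError(f"k={k} too large for {n - p} residual degrees of freedom")
    Y = compute_log_cpm(counts).values  # genes x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta  # samples x genes
    resid = resid - resid.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(resid, full_matrices=False)
    out = pd.DataFrame({"sample_id": counts.sample_ids})
    for i in range(k):
        v = u[:, i] - u[:, i].mean()
        nrm = np.linalg.norm(v)
        out[f"SV{i + 1}"] = v / nrm if nrm > 0 else v
    return out


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries (untested genes) are excluded from the denominator and
    returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# the NB Wald model


@dataclass
class DEResults:
    """Per-gene differential-expression results.

    ``table`` columns: gene_id, base_mean, log2fc, se, wald_stat, p, padj,
    flags.  Genes flagged as failed are excluded from the BH denominator and
    carry NaN p / padj.
    """

    table: pd.DataFrame
    contrast: str
    design_terms: list[str]
    size_factors: pd.DataFrame
    dispersion_trend: tuple[float, float]
    n_failed: int

    def summarize(self, fdr: float = 0.1, abs_fc: float = 2.0) -> dict:
        return summarize_deg(self.table, fdr=fdr, abs_fc=abs_fc)

    def significant(self, fdr: float = 0.1) -> pd.DataFrame:
        t = self.table
        return t[t["padj"] < fdr]

    def summary(self, fdr: float = 0.1) -> str:
        s = self.summarize(fdr=fdr)
        a0, a1 = self.dispersion_trend
        lines = [
            "NB Wald differential expression",
            f"  contrast:        {self.contrast}",
            f"  design terms:    {self.design_terms}",
            f"  genes tested:    {len(self.table) - self.n_failed}"
            f" (of {len(self.table)}; {self.n_failed} failed fits)",
            f"  dispersion trend: alpha(mu) = {a0:.4g} + {a1:.4g}/mu",
            f"  DEGs at FDR {fdr:g}: {s['n_deg']}"
            f" ({s['n_up']} up, {s['n_down']} down,"
            f" {s['n_abs_fc']} with |FC| > {s['abs_fc']:g})",
        ]
        return "\n".join(lines)


class NBDifferential:
    """Per-gene negative-binomial GLM with a Wald test on one design term.

    Parameters
    ----------
    counts
        Filtered count matrix (genes x samples).
    samples
        Sample metadata; rows are matched to count columns by sample_id.
    contrast
        Design term to test, ``"genotype"`` or ``"treatment"``.
    design_terms
        Terms entering the mean model; defaults to ``[contrast]``.
    covariates
        Optional DataFrame of extra real covariates (e.g. surrogates) with a
        sample_id column.
    """

    def __init__(
        self,
        counts: CountMatrix,
        samples: SampleTable,
        contrast: str = "genotype",
        design_terms: list[str] | None = None,
        covariates: pd.DataFrame | None = None,
    ) -> None:
        self.counts = counts
        self.samples = samples
        self.contrast = contrast
        self.design_terms = list(design_terms) if design_terms else [contrast]
        if contrast not in self.design_terms:
            raise ValueError(f"contrast {contrast!r} not among design terms")
        meta = samples.aligned(counts.sample_ids)
        X = design_matrix(meta, self.design_terms)
        names = ["intercept"] + self.design_terms
        if covariates is not None:
            cov = covariates.set_index("sample_id")
            extra = cov.loc[counts.sample_ids]
            for c in extra.columns:
                X = np.column_stack([X, extra[c].to_numpy(dtype=float)])
                names.append(str(c))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DataError("design plus covariates is rank deficient")
        self.exog = X
        self.exog_names = names
        self._ci = names.index(contrast)

    # -- dispersion ---------------------------------------------------------

    def _dispersions(self, sf: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
        """Method-of-moments per-gene dispersion, shrunk toward a 1/mu trend."""
        q = self.counts.counts / sf  # normalized counts, genes x samples
        X = self.exog
        n, p = X.shape
        # residual variance after removing design-cell means
        hat = X @ np.linalg.pinv(X)
        resid = q @ (np.eye(n) - hat).T
        s2 = (resid**2).sum(axis=1) / max(n - p, 1)
        mu = q.mean(axis=1)
        mu_safe = np.maximum(mu, 1e-8)
        raw = np.maximum((s2 - mu) / mu_safe**2, DISPERSION_FLOOR)
        # least-squares trend alpha = a0 + a1/mu over informative genes
        use = mu > 1
        if use.sum() >= 2:
            A = np.column_stack([np.ones(use.sum()), 1.0 / mu_safe[use]])
            coef, *_ = np.linalg.lstsq(A, raw[use], rcond=None)
            a0, a1 = float(max(coef[0], DISPERSION_FLOOR)), float(max(coef[1], 0.0))
        else:
            a0, a1 = 0.01, 2.0
        trend = a0 + a1 / mu_safe
        alpha = np.maximum(0.5 * raw + 0.5 * trend, DISPERSION_FLOOR)
        return alpha, (a0, a1)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> DEResults:
        counts = self.counts
        sf_table = estimate_size_factors(counts)
        sf = sf_table["size_factor"].to_numpy()
        offset = np.log(sf)
        X = self.exog
        n, p = X.shape
        if n <= p:
            raise DataError(f"{n} samples cannot identify {p} coefficients")
        y = counts.counts.astype(float)  # genes x samples
        alpha, trend = self._dispersions(sf)

        G = counts.n_genes
        # initialize from log of normalized group means via least squares
        q = np.log((y / sf) + 0.5)
        beta = np.linalg.lstsq(X, q.T, rcond=None)[0].T  # genes x p

        converged = np.zeros(G, dtype=bool)
        active = np.ones(G, dtype=bool)
        a = alpha[:, None]
        for _ in range(IRLS_MAXIT):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            eta = beta[idx] @ X.T + offset
            eta = np.clip(eta, -30.0, 30.0)
            mu = np.exp(eta)
            w = mu / (1.0 + a[idx] * mu)  # IRLS weights for NB2 log link
            score = ((y[idx] - mu) / (1.0 + a[idx] * mu)) @ X  # genes x p
            XtWX = np.einsum("gn,np,nq->gpq", w, X, X)
            try:
                step = np.linalg.solve(XtWX, score[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.stack(
                    [np.linalg.lstsq(XtWX[i], score[i], rcond=None)[0] for i in range(len(idx))]
                )
            beta[idx] += step
            gnorm = np.abs(score).max(axis=1)
            done = gnorm < IRLS_TOL
            converged[idx[done]] = True
            active[idx[done]] = False

        # final weights / Fisher information at the solution
        eta = beta @ X.T + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)
        XtWX = np.einsum("gn,np,nq->gpq", w, X, X)
        se = np.full(G, np.nan)
        ok = converged.copy()
        with np.errstate(all="ignore"):
            for g in np.flatnonzero(ok):
                try:
                    cov = np.linalg.inv(XtWX[g])
                    v = cov[self._ci, self._ci]
                    if v > 0 and np.isfinite(v):
                        se[g] = np.sqrt(v)
                    else:
                        ok[g] = False
                except np.linalg.LinAlgError:
                    ok[g] = False

        coef = beta[:, self._ci]
        log2fc = coef / _LN2
        se_log2 = se / _LN2
        with np.errstate(invalid="ignore", divide="ignore"):
            wald = np.where(ok, log2fc / se_log2, np.nan)
        pvals = np.where(ok, 2.0 * stats.norm.sf(np.abs(wald)), np.nan)
        padj = bh_adjust(pvals)

        flags = np.where(ok, "", "no_converge")
        zero_group = self._separation_flags()
        flags = np.where(zero_group & (flags == ""), "zero_group", flags)

        base_mean = (y / sf).mean(axis=1)
        table = pd.DataFrame(
            {
                "gene_id": counts.gene_ids,
                "base_mean": base_mean,
                "log2fc": log2fc,
                "se": se_log2,
                "wald_stat": wald,
                "p": pvals,
                "padj": padj,
                "flags": flags,
            }
        )
        return DEResults(
            table=table,
            contrast=self.contrast,
            design_terms=self.design_terms,
            size_factors=sf_table,
            dispersion_trend=trend,
            n_failed=int((~ok).sum()),
        )

    def _separation_flags(self) -> np.ndarray:
        """Flag genes where one contrast group is all zero (quasi-separation)."""
        grp = self.exog[:, self._ci] > 0.5
        y = self.counts.counts
        return (y[:, grp].sum(axis=1) == 0) | (y[:, ~grp].sum(axis=1) == 0)


def nb_wald_test(
    counts: CountMatrix,
    samples: SampleTable,
    covariates: pd.DataFrame | None = None,
    contrast: str = "genotype",
    design_terms: list[str] | None = None,
) -> pd.DataFrame:
    """Functional facade over :class:`NBDifferential`; returns the DEG table."""
    model = NBDifferential(
        counts,
        samples,
        contrast=contrast,
        design_terms=design_terms,
        covariates=covariates,
    )
    return model.fit().table


def summarize_deg(table: pd.DataFrame, fdr: float = 0.1, abs_fc: float = 2.0) -> dict:
    """Counts of significant genes, split by fold-change sign and magnitude."""
    sig = table[table["padj"] < fdr]
    n_up = int((sig["log2fc"] > 0).sum())
    n_down = int((sig["log2fc"] < 0).sum())
    n_big = int((sig["log2fc"].abs() > np.log2(abs_fc)).sum())
    return {
        "fdr": fdr,
        "abs_fc": abs_fc,
        "n_deg": int(len(sig)),
        "n_up": n_up,
        "n_down": n_down,
        "n_abs_fc": n_big,
    }


def stratum_contrast(
    counts: CountMatrix, samples: SampleTable, contrast: str
) -> tuple[CountMatrix, SampleTable]:
    """Restrict to the per-stratum comparison for a named contrast.

    genotype: HET vs WT among VEHICLE samples; treatment: DRUG vs VEHICLE
    among HET samples.  If the stratifying column has a single level the full
    matrix is returned.
    """
    meta = samples.aligned(counts.sample_ids)
    if contrast == "genotype":
        if meta["treatment"].nunique() > 1:
            keep = meta["treatment"] == "VEHICLE"
        else:
            keep = pd.Series(True, index=meta.index)
    elif contrast == "treatment":
        if meta["genotype"].nunique() > 1:
            keep = meta["genotype"] == "HET"
        else:
            keep = pd.Series(True, index=meta.index)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    ids = list(meta.loc[keep, "sample_id"])
    sub_counts = counts.subset_samples(ids)
    sub_samples = SampleTable(meta.loc[keep].reset_index(drop=True))
    return sub_counts, sub_samples
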