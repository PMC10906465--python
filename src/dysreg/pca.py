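"""Expression PCA and phenotype correlation.

PCA runs on log2(CPM + 1) over all expressed genes: genes are mean-centered
(no unit-variance scaling) and the sample-space scores come from an SVD of
the centered matrix.  Components are oriented so the largest-magnitude
sample score is positive, which pins the otherwise arbitrary sign of
downstream correlations.  Phenotype correlations are Pearson throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, ExpressionMatrix, GeneSet, SampleTable
from .setperm import DysregulationResult


@dataclass
class PCAResult:
    sample_ids: list[str]
    component_scores: np.ndarray  # samples x k
    variance_fraction: np.ndarray  # length k
    gene_loadings: np.ndarray  # genes x k
    gene_ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.component_scores,
            columns=[f"PC{i + 1}" for i in range(self.component_scores.shape[1])],
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def summary(self) -> str:
        parts = ", ".join(
            f"PC{i + 1} {f * 100:.1f}%" for i, f in enumerate(self.variance_fraction)
        )
        return f"PCA of log2-CPM (genes centered): {parts}"


def pca_expression(expr: ExpressionMatrix, k: int) -> PCAResult:
    """SVD-based PCA of a gene-by-sample expression matrix."""
    n = len(expr.sample_ids)
    if n < 2:
        raise DataError("PCA needs at least 2 samples")
    if not 1 <= k < n:
        raise DataError(f"k must lie in [1, {n - 1}]")
    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise DataError("expression matrix is constant; PCA undefined")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    scores = vt.T * s  # samples x components
    # orient: largest-|score| sample positive
    for i in range(scores.shape[1]):
        j = int(np.argmax(np.abs(scores[:, i])))
        if scores[j, i] < 0:
            scores[:, i] = -scores[:, i]
            u[:, i] = -u[:, i]
    return PCAResult(
        sample_ids=list(expr.sample_ids),
        component_scores=scores[:, :k],
        variance_fraction=frac[:k],
        gene_loadings=u[:, :k],
        gene_ids=list(expr.gene_ids),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("correlation undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def pc_phenotype_correlation(
    pca: PCAResult, samples: SampleTable, component: int = 1
) -> float:
    """Pearson correlation between one component's sample scores and the
    per-sample phenotype."""
    if not 1 <= component <= pca.component_scores.shape[1]:
        raise ValueError(f"component must lie in [1, {pca.component_scores.shape[1]}]")
    pheno = samples.phenotype_for(pca.sample_ids)
    return _pearson(pca.component_scores[:, component - 1], pheno)


def gene_phenotype_correlations(
    expr: ExpressionMatrix, samples: SampleTable, pca: PCAResult
) -> pd.DataFrame:
    """Per-gene Pearson r against phenotype and against PC1 scores.

    Zero-variance genes get NaN correlations and rank last.
    """
    pheno = samples.phenotype_for(expr.sample_ids)
    pc1 = pca.component_scores[:, 0]
    X = expr.values
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    ok = sx > 0

    def corr_with(v: np.ndarray) -> np.ndarray:
        vc = v - v.mean()
        sv = np.sqrt((vc**2).sum())
        if sv == 0:
            raise DataError("correlation undefined: zero-variance vector")
        r = np.full(X.shape[0], np.nan)
        r[ok] = (Xc[ok] @ vc) / (sx[ok] * sv)
        return r

    r_ph = corr_with(pheno)
    r_pc1 = corr_with(pc1)
    df = pd.DataFrame(
        {"gene_id": expr.gene_ids, "r_phenotype": r_ph, "r_pc1": r_pc1}
    )
    df["rank_phenotype"] = (
        df["r_phenotype"].rank(ascending=False, na_option="bottom", method="first")
    ).astype(int)
    df["rank_abs_pc1"] = (
        df["r_pc1"].abs().rank(ascending=False, na_option="bottom", method="first")
    ).astype(int)
    return df


def top_correlated(corr: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """The k genes with the highest positive phenotype correlation."""
    return corr.nsmallest(k, "rank_phenotype")


def set_correlation_enrichment(
    corr: pd.DataFrame,
    gene_set: GeneSet,
    B: int = 1000,
    seed: int = 0,
) -> DysregulationResult:
    """Is the set's mean |r| with PC1 high relative to random equal-size sets?

    Observed statistic: mean |r_pc1| over set members.  Null: the same over
    ``B`` random subsets of tested genes; add-one empirical p counting null
    draws >= observed (ties count as extreme).
    """
    tested = corr.dropna(subset=["r_pc1"]).copy()
    tested = tested.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    members = gene_set.members & set(tested["gene_id"])
    if not members:
        raise DataError(
            f"gene set {gene_set.name!r} shares no members with the tested genes"
        )
    mask = tested["gene_id"].isin(members).to_numpy()
    absr = tested["r_pc1"].abs().to_numpy()
    n = absr.size
    n1 = int(mask.sum())
    observed = float(absr[mask].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    if n1 == n:
        null.fill(observed)
    else:
        chunk = max(1, min(B, 512))
        done = 0
        while done < B:
            m = min(chunk, B - done)
            keys = rng.random((m, n))
            idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
            null[done : done + m] = absr[idx].mean(axis=1)
            done += m
    emp_p = (1 + int((null >= observed).sum())) / (B + 1)
    return DysregulationResult(
        set_name=gene_set.name,
        n_in_set_expressed=n1,
        observed_stat=observed,
        null_stats=null,
        empirical_p=float(emp_p),
        B=B,
        seed=seed,
        sidedness="high_abs_r",
    )
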