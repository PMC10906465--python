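"""Cross-contrast analyses: conditional p-value enrichment and
fold-change-reversal counting for a pharmacological rescue.

``reversal_analysis`` takes two DEG tables (e.g. HET-vehicle vs WT-vehicle,
and HET-drug vs HET-vehicle), intersects their significant genes, and
classifies each shared gene by whether its log2 fold-changes have strictly
opposite signs — the operational readout of transcriptional rescue.

``conditional_p_enrichment`` stratifies one experiment's p-values by
significance in a second (conditioning) experiment and compares the strata
with a two-sample Kolmogorov-Smirnov test; an excess of low p-values in the
conditioned-significant stratum indicates shared signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet


@dataclass
class ConditionalEnrichment:
    n_shared_genes: int
    n_conditioning_sig: int
    n_conditioning_nonsig: int
    ecdf_grid: np.ndarray
    ecdf_sig: np.ndarray | None
    ecdf_nonsig: np.ndarray | None
    ks_stat: float | None
    ks_p: float | None
    defined: bool

    def summary(self) -> str:
        if not self.defined:
            return (
                "Conditional p-value enrichment: undefined "
                f"(strata sizes {self.n_conditioning_sig} / "
                f"{self.n_conditioning_nonsig})"
            )
        return (
            "Conditional p-value enrichment\n"
            f"  shared genes: {self.n_shared_genes}\n"
            f"  conditioning-significant stratum: {self.n_conditioning_sig}\n"
            f"  KS statistic: {self.ks_stat:.4f} (p = {self.ks_p:.3g})"
        )


@dataclass
class ReversalResult:
    shared_gene_ids: list[str]
    n_shared: int
    n_reversed: int
    n_concordant: int
    per_gene: pd.DataFrame  # gene_id, log2fc_A, log2fc_B, reversed
    set_overlaps: dict[str, int]

    @property
    def reversal_fraction(self) -> float:
        return self.n_reversed / self.n_shared if self.n_shared else float("nan")

    def summary(self) -> str:
        lines = [
            "Fold-change reversal analysis",
            f"  shared significant genes: {self.n_shared}",
            f"  reversed: {self.n_reversed}  concordant: {self.n_concordant}",
        ]
        if self.n_shared:
            lines.append(f"  reversal fraction: {self.reversal_fraction:.3f}")
        for name, k in self.set_overlaps.items():
            lines.append(f"  shared genes in set {name!r}: {k}")
        return "\n".join(lines)


def conditional_p_enrichment(
    table_primary: pd.DataFrame,
    table_conditioning: pd.DataFrame,
    fdr: float = 0.1,
    grid_size: int = 101,
) -> ConditionalEnrichment:
    """Stratify primary-experiment p-values by conditioning significance."""
    a = table_primary.set_index("gene_id")
    b = table_conditioning.set_index("gene_id")
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("the two DEG tables share no genes")
    p_primary = a.loc[shared, "p"].to_numpy(dtype=float)
    padj_cond = b.loc[shared, "padj"].to_numpy(dtype=float)
    keep = ~np.isnan(p_primary) & ~np.isnan(padj_cond)
    p_primary, padj_cond = p_primary[keep], padj_cond[keep]
    sig = padj_cond < fdr
    grid = np.linspace(0.0, 1.0, grid_size)
    n_sig, n_non = int(sig.sum()), int((~sig).sum())
    if n_sig == 0 or n_non == 0:
        return ConditionalEnrichment(
            n_shared_genes=int(keep.sum()),
            n_conditioning_sig=n_sig,
            n_conditioning_nonsig=n_non,
            ecdf_grid=grid,
            ecdf_sig=None,
            ecdf_nonsig=None,
            ks_stat=None,
            ks_p=None,
            defined=False,
        )
    p_sig, p_non = p_primary[sig], p_primary[~sig]
    ecdf_sig = np.searchsorted(np.sort(p_sig), grid, side="right") / n_sig
    ecdf_non = np.searchsorted(np.sort(p_non), grid, side="right") / n_non
    ks = stats.ks_2samp(p_sig, p_non)
    return ConditionalEnrichment(
        n_shared_genes=int(keep.sum()),
        n_conditioning_sig=n_sig,
        n_conditioning_nonsig=n_non,
        ecdf_grid=grid,
        ecdf_sig=ecdf_sig,
        ecdf_nonsig=ecdf_non,
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        defined=True,
    )


def reversal_analysis(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    fdr: float = 0.1,
    gene_sets: list[GeneSet] | None = None,
) -> ReversalResult:
    """Count sign reversals among genes significant in both contrasts.

    Reversed means strictly opposite log2fc signs (product < 0); a zero
    fold-change in either contrast counts as concordant.
    """
    a = table_a.set_index("gene_id")
    b = table_b.set_index("gene_id")
    shared_idx = a.index[a["padj"] < fdr].intersection(b.index[b["padj"] < fdr])
    shared = sorted(shared_idx)
    lfc_a = a.loc[shared, "log2fc"].to_numpy(dtype=float)
    lfc_b = b.loc[shared, "log2fc"].to_numpy(dtype=float)
    reversed_mask = lfc_a * lfc_b < 0
    per_gene = pd.DataFrame(
        {
            "gene_id": shared,
            "log2fc_A": lfc_a,
            "log2fc_B": lfc_b,
            "reversed": reversed_mask,
        }
    )
    overlaps: dict[str, int] = {}
    if gene_sets:
        shared_set = set(shared)
        for gs in gene_sets:
            overlaps[gs.name] = len(shared_set & gs.members)
    return ReversalResult(
        shared_gene_ids=list(shared),
        n_shared=len(shared),
        n_reversed=int(reversed_mask.sum()),
        n_concordant=int((~reversed_mask).sum()),
        per_gene=per_gene,
        set_overlaps=overlaps,
    )
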