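"""Promoter windows around TSS and overlap-based target-gene calling.

A gene is a target of a factor when its promoter (+/- flank around the
TSS, default 2 kb) shares at least one base with any binding-site cluster
on the same chromosome.  All coordinates are 0-based half-open; touching
intervals do not overlap.  Cluster strand is ignored (TFBS cluster tracks
are unstranded); the window is symmetric about the TSS regardless of the
gene's strand.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .io import DataError, GenomicInterval


def define_promoters(
    tss: list[GenomicInterval], flank: int = 2000
) -> dict[str, GenomicInterval]:
    """Promoter window [tss - flank, tss + flank) per gene, clipped at 0.

    TSS records must be single positions (end = start + 1) with strand
    + or -; the TSS coordinate is the interval start.
    """
    if flank <= 0:
        raise DataError("flank must be positive")
    promoters: dict[str, GenomicInterval] = {}
    for iv in tss:
        if iv.end != iv.start + 1:
            raise DataError(
                f"TSS record {iv.name!r} spans {len(iv)} bases; expected 1"
            )
        if iv.strand not in ("+", "-"):
            raise DataError(f"TSS record {iv.name!r} lacks a strand")
        if iv.name is None:
            raise DataError("TSS records must carry a gene name")
        if iv.name in promoters:
            raise DataError(f"duplicate TSS record for gene {iv.name!r}")
        start = max(iv.start - flank, 0)
        promoters[iv.name] = GenomicInterval(
            iv.chrom, start, iv.start + flank, iv.strand, iv.name
        )
    return promoters


def flag_targets(
    promoters: dict[str, GenomicInterval], clusters: list[GenomicInterval]
) -> dict[str, bool]:
    """gene_id -> True iff any same-chromosome cluster overlaps its promoter.

    Half-open overlap: cluster.start < promoter.end and
    promoter.start < cluster.end.  Implemented as a per-chromosome sorted
    sweep using a prefix maximum of cluster ends, O((n + m) log(n + m)).
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for c in clusters:
        by_chrom[c.chrom].append(c)
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, cs in by_chrom.items():
        starts = np.array(sorted(c.start for c in cs))
        order = np.argsort([c.start for c in cs], kind="mergesort")
        ends = np.array([cs[i].end for i in order])
        prefix_max_end = np.maximum.accumulate(ends)
        index[chrom] = (starts, prefix_max_end)
    flags: dict[str, bool] = {}
    for gene, prom in promoters.items():
        entry = index.get(prom.chrom)
        if entry is None:
            flags[gene] = False
            continue
        starts, prefix_max_end = entry
        # clusters with start < prom.end; overlap iff the max end among them
        # exceeds prom.start
        k = int(np.searchsorted(starts, prom.end, side="left"))
        flags[gene] = k > 0 and prefix_max_end[k - 1] > prom.start
    return flags
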