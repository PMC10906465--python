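"""Domain containers and plain-text readers/writers.

The pipeline works on gene-by-sample integer count matrices with a sample
metadata table (genotype in {WT, HET}, treatment in {VEHICLE, DRUG}), gene
sets (plain lists or GMT), and genomic intervals (BED3/BED6).  Genomic
coordinates are 0-based half-open everywhere, exactly as in BED.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "HET")
TREATMENTS = ("VEHICLE", "DRUG")
STRANDS = ("+", "-", ".")

_SEPS = {"tsv": "\t", "csv": ","}


class DataError(ValueError):
    """Malformed or contract-violating input data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Non-negative integer gene-by-sample count matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)):
                raise DataError("counts contain non-finite values")
            rounded = np.rint(self.counts)
            if not np.array_equal(rounded, self.counts):
                raise DataError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise DataError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        genes = [g for g, k in zip(self.gene_ids, keep) if k] if keep.dtype == bool \
            else [self.gene_ids[i] for i in keep]
        return CountMatrix(genes, list(self.sample_ids), self.counts[keep])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class ExpressionMatrix:
    """Real-valued gene-by-sample matrix, typically log2(CPM + pseudocount)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("expression matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleTable:
    """Per-sample metadata: genotype, treatment, technical-replicate group,
    and an optional mineralization phenotype (Alizarin-red absorbance)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("sample_id", "genotype", "treatment"):
            if col not in df.columns:
                raise DataError(f"sample table missing required column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        for col, vocab in (("genotype", GENOTYPES), ("treatment", TREATMENTS)):
            bad = set(df[col]) - set(vocab)
            if bad:
                raise DataError(f"unknown {col} value(s) {sorted(bad)}; allowed: {vocab}")
        if "replicate_group" not in df.columns:
            df["replicate_group"] = df["sample_id"]
        if "phenotype" in df.columns:
            pheno = pd.to_numeric(df["phenotype"], errors="raise")
            if not np.all(np.isfinite(pheno.to_numpy(dtype=float))):
                raise DataError("phenotype values must be finite")
            df["phenotype"] = pheno.astype(float)
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def has_phenotype(self) -> bool:
        return "phenotype" in self.frame.columns

    def phenotype_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        if not self.has_phenotype:
            raise DataError("sample table has no phenotype column")
        s = self.frame.set_index("sample_id")["phenotype"]
        return s.loc[list(sample_ids)].to_numpy(dtype=float)

    def aligned(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Metadata rows reordered to a count matrix's sample order."""
        df = self.frame.set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise DataError(f"samples missing from sample table: {missing}")
        return df.loc[list(sample_ids)].reset_index()


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise DataError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("interval chromosome name is empty")
        if self.start < 0:
            raise DataError(f"negative interval start {self.start}")
        if self.end <= self.start:
            raise DataError(f"interval end {self.end} must exceed start {self.start}")
        if self.strand not in STRANDS:
            raise DataError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a gene-by-sample count table; first column gene ids, header samples."""
    sep = _SEPS[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise DataError(
            f"non-numeric or missing count for gene {gene_ids[g]!r}, "
            f"sample {sample_ids[s]!r}"
        )
    values = numeric.to_numpy()
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise DataError(
            f"negative count for gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )
    if not np.issubdtype(values.dtype, np.integer):
        if not np.array_equal(np.rint(values), values):
            g, s = np.argwhere(np.rint(values) != values)[0]
            raise DataError(
                f"non-integer count for gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
            )
        values = np.rint(values).astype(np.int64)
    return CountMatrix(gene_ids, sample_ids, values)


def read_sample_table(path: str | Path, dialect: str = "tsv") -> SampleTable:
    df = pd.read_csv(path, sep=_SEPS[dialect], comment="#")
    return SampleTable(df)


def read_gene_set(path: str | Path, format: str = "list"):
    """Read gene sets: ``list`` (one id per line) -> GeneSet;
    ``gmt`` (name, description, members per line) -> list of GeneSet."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise DataError(f"gene-set file {path} is empty")
    if format == "list":
        members = [line.strip() for line in text.splitlines() if line.strip()]
        return GeneSet(path.stem, frozenset(members))
    if format == "gmt":
        sets = []
        for i, line in enumerate(text.splitlines(), start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataError(f"malformed GMT line {i} in {path}: needs >= 3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name, frozenset(members)))
        return sets
    raise ValueError(f"unknown gene-set format {format!r}")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+; coordinates kept 0-based half-open, strand '.' when absent."""
    intervals = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataError(f"BED line {i}: fewer than 3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else None
        strand = fields[5] if len(fields) > 5 else "."
        try:
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
        except DataError as exc:
            raise DataError(f"BED line {i}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def combine_technical_replicates(
    counts: CountMatrix, samples: SampleTable
) -> tuple[CountMatrix, SampleTable]:
    """Sum count columns that share a replicate_group.

    Merged samples must agree on genotype and treatment; the merged column is
    named after the replicate group.  Total counts are conserved.
    """
    meta = samples.aligned(counts.sample_ids)
    groups = list(dict.fromkeys(meta["replicate_group"]))
    new_cols = np.zeros((counts.n_genes, len(groups)), dtype=np.int64)
    rows = []
    for j, grp in enumerate(groups):
        mask = (meta["replicate_group"] == grp).to_numpy()
        sub = meta[mask]
        for col in ("genotype", "treatment"):
            if sub[col].nunique() != 1:
                raise DataError(
                    f"replicate group {grp!r} mixes {col} values "
                    f"{sorted(sub[col].unique())}"
                )
        new_cols[:, j] = counts.counts[:, mask].sum(axis=1)
        row = {
            "sample_id": str(grp),
            "genotype": sub["genotype"].iloc[0],
            "treatment": sub["treatment"].iloc[0],
            "replicate_group": str(grp),
        }
        if "phenotype" in meta.columns:
            row["phenotype"] = float(sub["phenotype"].mean())
        rows.append(row)
    merged = CountMatrix(list(counts.gene_ids), [str(g) for g in groups], new_cols)
    return merged, SampleTable(pd.DataFrame(rows))


def write_result_table(
    table: pd.DataFrame, path: str | Path, dialect: str = "tsv", comment: str | None = None
) -> None:
    """Write a result table deterministically: sorted by ``rank`` column if
    present, else by gene_id/index; floats at full precision."""
    if table is None or len(table) == 0:
        raise DataError("refusing to write an empty result table")
    df = table.copy()
    if "rank" in df.columns:
        df = df.sort_values("rank", kind="mergesort")
    elif "gene_id" in df.columns:
        df = df.sort_values("gene_id", kind="mergesort")
    else:
        df = df.sort_index(kind="mergesort")
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=_SEPS[dialect], index=False, float_format="%.15g")


def read_result_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEPS[dialect], comment="#")
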