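"""End-to-end orchestration: ingest (or simulate) -> replicate merge ->
filter -> DE per contrast -> gene-set dysregulation -> reversal -> PCA ->
promoter-overlap targets, with a manifest recording config, seed and
output checksums so identical runs are byte-identical."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, intervals, pca, reversal, setperm
from .io import (
    CountMatrix,
    DataError,
    SampleTable,
    combine_technical_replicates,
    read_bed,
    read_count_table,
    read_gene_set,
    read_sample_table,
    write_result_table,
)

log = logging.getLogger("dysreg")

EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_NUMERIC = 4


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    counts: str | None = None
    samples: str | None = None
    gene_set: str | None = None
    gene_set_format: str = "list"
    tss: str | None = None
    clusters: str | None = None
    out_dir: str = "dysreg_out"
    fdr: float = 0.1
    min_median: int = 10
    n_sv: int = 2
    B: int = 10_000
    seed: int = 0
    flank: int = 2000
    contrasts: list[str] = field(default_factory=lambda: ["genotype", "treatment"])
    sidedness: str = "two_sided"
    pca_k: int = 5

    def validate(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ConfigError(f"fdr must lie in (0, 1); got {self.fdr}")
        if self.B < 100:
            raise ConfigError(f"B must be >= 100; got {self.B}")
        if self.min_median < 0:
            raise ConfigError("min_median must be non-negative")
        if self.n_sv < 0:
            raise ConfigError("n_sv must be non-negative")
        for c in self.contrasts:
            if c not in ("genotype", "treatment"):
                raise ConfigError(f"unknown contrast {c!r}")
        for key in ("counts", "samples", "gene_set", "tss", "clusters"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"{key} path does not exist: {val}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run manifest."""
    config.validate()
    if config.counts is None or config.samples is None:
        raise ConfigError("counts and samples paths are required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    manifest: dict = {"config": asdict(config), "stages": [], "outputs": {}}
    stage = "load"
    try:
        counts = read_count_table(config.counts)
        samples = read_sample_table(config.samples)
        log.info("loaded %d genes x %d samples", counts.n_genes, counts.n_samples)
        manifest["stages"].append(stage)

        stage = "combine_replicates"
        counts, samples = combine_technical_replicates(counts, samples)
        manifest["stages"].append(stage)

        stage = "filter"
        filtered = de.filter_low_expressed(counts, config.min_median)
        log.info("filter kept %d of %d genes", filtered.n_genes, counts.n_genes)
        manifest["stages"].append(stage)

        tables: dict[str, pd.DataFrame] = {}
        meta = samples.aligned(filtered.sample_ids)
        for contrast in config.contrasts:
            stage = f"de_{contrast}"
            strat = contrast == "treatment" and meta["genotype"].nunique() > 1
            sub_counts, sub_samples = de.stratum_contrast(filtered, samples, contrast)
            sub_meta = sub_samples.frame
            if contrast == "treatment" and sub_meta["treatment"].nunique() < 2:
                log.info("skipping contrast %s: single treatment level", contrast)
                continue
            if contrast == "genotype" and sub_meta["genotype"].nunique() < 2:
                log.info("skipping contrast %s: single genotype level", contrast)
                continue
            cov = (
                de.estimate_surrogates(sub_counts, sub_samples, [contrast], config.n_sv)
                if config.n_sv > 0
                else None
            )
            model = de.NBDifferential(
                sub_counts, sub_samples, contrast=contrast, covariates=cov
            )
            res = model.fit()
            tables[contrast] = res.table
            summ = res.summarize(fdr=config.fdr)
            manifest[f"summary_{contrast}"] = summ
            path = out / f"deg_{contrast}.tsv"
            write_result_table(
                res.table, path, comment=f"stage={stage} fdr={config.fdr} n_sv={config.n_sv}"
            )
            manifest["outputs"][path.name] = _sha256(path)
            manifest["stages"].append(stage)
            log.info("%s: %s", contrast, res.summary(fdr=config.fdr))

        if config.gene_set and tables:
            stage = "set_dysregulation"
            gs = read_gene_set(config.gene_set, config.gene_set_format)
            gene_sets = gs if isinstance(gs, list) else [gs]
            rows = []
            first_contrast = next(iter(tables))
            for s in gene_sets:
                r = setperm.set_dysregulation_test(
                    tables[first_contrast],
                    s,
                    B=config.B,
                    seed=config.seed,
                    sidedness=config.sidedness,
                )
                rows.append(
                    {
                        "set_name": r.set_name,
                        "n_expressed": r.n_in_set_expressed,
                        "observed_z": r.observed_stat,
                        "empirical_p": r.empirical_p,
                        "B": r.B,
                    }
                )
                log.info(r.summary())
            path = out / "set_dysregulation.tsv"
            write_result_table(
                pd.DataFrame(rows), path, comment=f"stage={stage} B={config.B} seed={config.seed}"
            )
            manifest["outputs"][path.name] = _sha256(path)
            manifest["stages"].append(stage)

        if {"genotype", "treatment"} <= set(tables):
            stage = "reversal"
            rr = reversal.reversal_analysis(
                tables["genotype"], tables["treatment"], fdr=config.fdr
            )
            manifest["reversal"] = {
                "n_shared": rr.n_shared,
                "n_reversed": rr.n_reversed,
                "n_concordant": rr.n_concordant,
            }
            if rr.n_shared:
                path = out / "reversal.tsv"
                write_result_table(
                    rr.per_gene, path, comment=f"stage={stage} fdr={config.fdr}"
                )
                manifest["outputs"][path.name] = _sha256(path)
            log.info(rr.summary())
            manifest["stages"].append(stage)

        stage = "pca"
        expr = de.compute_log_cpm(filtered)
        k = min(config.pca_k, len(filtered.sample_ids) - 1)
        pres = pca.pca_expression(expr, k)
        manifest["pca_variance_fraction"] = [float(v) for v in pres.variance_fraction]
        path = out / "pca_scores.tsv"
        df = pres.scores_frame()
        df.to_csv(path, sep="\t", index=False, float_format="%.15g")
        manifest["outputs"][path.name] = _sha256(path)
        if samples.has_phenotype:
            r = pca.pc_phenotype_correlation(pres, samples)
            manifest["pc1_phenotype_r"] = float(r)
            corr = pca.gene_phenotype_correlations(expr, samples, pres)
            path = out / "gene_correlations.tsv"
            write_result_table(corr, path, comment="stage=pca")
            manifest["outputs"][path.name] = _sha256(path)
            log.info("PC1-phenotype r = %.4f", r)
        manifest["stages"].append(stage)
        log.info(pres.summary())

        if config.tss and config.clusters:
            stage = "targets"
            tss = read_bed(config.tss)
            clusters = read_bed(config.clusters)
            promoters = intervals.define_promoters(tss, config.flank)
            flags = intervals.flag_targets(promoters, clusters)
            path = out / "targets.tsv"
            write_result_table(
                pd.DataFrame(
                    {
                        "gene_id": list(flags),
                        "is_target": [bool(v) for v in flags.values()],
                    }
                ),
                path,
                comment=f"stage={stage} flank={config.flank}",
            )
            manifest["outputs"][path.name] = _sha256(path)
            manifest["n_targets"] = int(sum(flags.values()))
            manifest["stages"].append(stage)
    except ConfigError:
        raise
    except DataError as exc:
        raise DataError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
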