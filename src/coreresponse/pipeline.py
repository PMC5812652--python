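"""End-to-end pipeline: simulate -> normalize -> DE -> core sets -> kinetics
-> PCA -> motif scan, with one seed governing all randomness and a summary
report. All outputs are TSV with a parameter/seed header, so two runs with
the same configuration are byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from . import data_io, de_engine, kinetics, motif_scan, normalization, ordination
from . import response_sets, synthetic_data

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults."""

    seed: int = 0
    n_genes: int = 2000
    fdr: float = 0.05
    prior_count: float = 0.5
    cpm_threshold: float = 1.2
    trim_m: float = 0.30
    trim_a: float = 0.05
    shrinkage: float = 0.7
    core_cutoff: int = 7
    theta_plat: float = 0.75
    theta_cont: float = 1.25
    pca_prior: float = 1.0
    top_n: int = 100
    motif: str = "TGCCACGT"
    promoter_length: int = 4000
    promoter_gc: float = 0.43
    planted_motif_fraction: float = 0.2
    counts_path: str | None = None  # simulate when absent
    samples_path: str | None = None
    external_list_path: str | None = None

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.fdr <= 1.0, "fdr must be in (0, 1]"),
            (self.prior_count >= 0, "prior_count must be >= 0"),
            (self.cpm_threshold >= 0, "cpm_threshold must be >= 0"),
            (0.0 <= self.trim_m < 0.5, "trim_m must be in [0, 0.5)"),
            (0.0 <= self.trim_a < 0.5, "trim_a must be in [0, 0.5)"),
            (0.0 <= self.shrinkage <= 1.0, "shrinkage must be in [0, 1]"),
            (self.core_cutoff >= 1, "core_cutoff must be >= 1"),
            (0 < self.theta_plat < self.theta_cont, "need 0 < theta_plat < theta_cont"),
            (self.top_n >= 1, "top_n must be >= 1"),
            (self.n_genes >= 10, "n_genes must be >= 10"),
            (0 < self.promoter_gc < 1, "promoter_gc must be in (0, 1)"),
            (
                0 <= self.planted_motif_fraction <= 1,
                "planted_motif_fraction must be in [0, 1]",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def header(self) -> dict:
        h = {f.name: getattr(self, f.name) for f in fields(self)}
        h["version"] = __version__
        return h


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, exc) from exc
            log.info("stage %s: %.2f s", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage in dependency order; returns the summary report dict.

    Writes all module outputs under ``outdir``. A stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = config.header()
    report: dict = {}

    # ---- inputs (simulate or load) ----
    @_stage("input")
    def _input():
        if config.counts_path:
            counts = data_io.read_counts(config.counts_path)
            samples = data_io.read_samplesheet(config.samples_path)
            truth = None
        else:
            sim = synthetic_data.SimConfig(n_genes=config.n_genes, seed=config.seed)
            counts, samples, truth = synthetic_data.simulate_experiment(sim)
            data_io.write_counts(counts, outdir / "counts.tsv", params=hdr)
            data_io.write_samplesheet(samples, outdir / "samples.tsv", params=hdr)
            data_io.write_table(truth.genes, outdir / "truth_genes.tsv", params=hdr)
            data_io.write_table(truth.lfc, outdir / "truth_lfc.tsv", params=hdr)
        return counts, samples, truth

    counts, samples, truth = _input()
    design = data_io.build_design(counts, samples)

    # ---- normalization ----
    @_stage("normalize")
    def _normalize():
        filtered = normalization.filter_low_counts(
            counts, config.cpm_threshold, design.smallest_group_size()
        )
        factors = normalization.tmm_factors(filtered, config.trim_m, config.trim_a)
        fdf = pd.DataFrame(
            {
                "sample_id": factors.sample_ids,
                "lib_size": factors.lib_size,
                "tmm_factor": factors.factors,
            }
        )
        data_io.write_table(fdf, outdir / "factors.tsv", params=hdr)
        data_io.write_counts(filtered, outdir / "filtered_counts.tsv", params=hdr)
        return filtered, factors

    filtered, factors = _normalize()

    # ---- differential expression ----
    @_stage("de")
    def _de():
        disp = de_engine.estimate_dispersion(filtered, design, factors, config.shrinkage)
        de = de_engine.run_all_contrasts(
            filtered, design, factors, disp, config.fdr, config.prior_count
        )
        data_io.write_table(de, outdir / "de_table.tsv", params=hdr)
        return disp, de

    disp, de = _de()
    report["n_genes_tested"] = filtered.n_genes
    report["n_contrasts"] = len(design.contrasts)
    report["n_de_genes"] = len(response_sets.de_gene_set(de, list({c for c, _ in design.contrasts})))

    # ---- core / unique / partitions ----
    @_stage("core")
    def _core():
        live = design.live_conditions()
        support = response_sets.condition_support(de, live)
        core = response_sets.define_core(support, config.core_cutoff)
        sweep = response_sets.cutoff_sweep(support)
        uniq = response_sets.unique_genes(de, live)
        gram = response_sets.gram_partition(support, design.pgn_map())
        wound = response_sets.de_gene_set(de, design.conditions_of_type("sterile_wound"))
        hk = response_sets.de_gene_set(de, design.conditions_of_type("heat_killed"))
        external = (
            data_io.read_gene_list(config.external_list_path)
            if config.external_list_path
            else None
        )
        venn = response_sets.overlap_report(
            core.genes, wound, hk, set(filtered.gene_ids), external
        )
        data_io.write_table(support.table, outdir / "support.tsv", params=hdr)
        data_io.write_table(core.members, outdir / "core.tsv", params=hdr)
        data_io.write_table(sweep, outdir / "core_sweep.tsv", params=hdr)
        data_io.write_table(uniq, outdir / "unique.tsv", params=hdr)
        gram_df = pd.DataFrame(
            [{"set": k, "n": len(v), "genes": ",".join(sorted(v))} for k, v in gram.items()]
        )
        data_io.write_table(gram_df, outdir / "gram.tsv", params=hdr)
        venn_df = pd.DataFrame(
            [{"cell": k, "n": v} for k, v in venn.items()]
        )
        data_io.write_table(venn_df, outdir / "venn.tsv", params=hdr)
        return support, core, sweep, uniq, gram, venn

    support, core, sweep, uniq, gram, venn = _core()
    report["core_size"] = len(core.members)
    report["core_up"] = core.count("up")
    report["core_down"] = core.count("down")
    for r in sweep.itertuples(index=False):
        report[f"core_n_at_cutoff_{r.cutoff}"] = r.n_total
    report["unique_total"] = int(uniq["n_unique"].sum())
    report["gram_lys_only"] = len(gram["lys_only"])
    report["gram_dap_only"] = len(gram["dap_only"])
    report["gram_both"] = len(gram["both"])

    # ---- kinetics ----
    @_stage("kinetics")
    def _kinetics():
        conds = design.three_timepoint_conditions()
        calls = kinetics.classify_all(de, conds, config.theta_plat, config.theta_cont)
        rec = kinetics.recovery_fractions(calls)
        traj = kinetics.trajectory_table(calls, core.genes)
        data_io.write_table(calls, outdir / "trajectory_calls.tsv", params=hdr)
        data_io.write_table(rec, outdir / "recovery_fractions.tsv", params=hdr)
        data_io.write_table(
            traj.reset_index(), outdir / "trajectory_matrix.tsv", params=hdr
        )
        return calls, rec

    calls, rec = _kinetics()
    for r in rec.itertuples(index=False):
        report[f"pct_recovered_{r.condition}"] = round(r.pct_recovered, 2)

    # ---- ordination ----
    @_stage("pca")
    def _pca():
        mat = ordination.expression_matrix(filtered, factors, config.pca_prior)
        pca = ordination.run_pca(mat, filtered.gene_ids, filtered.sample_ids)
        scores = pd.DataFrame(
            pca.scores[:, : min(10, pca.scores.shape[1])],
            index=pca.sample_ids,
        )
        data_io.write_table(
            scores.reset_index(names="sample_id"), outdir / "pca_scores.tsv", params=hdr
        )
        var_df = pd.DataFrame(
            {
                "component": range(1, len(pca.variance_explained) + 1),
                "variance_fraction": pca.variance_explained,
            }
        )
        data_io.write_table(var_df, outdir / "pca_variance.tsv", params=hdr)
        for pc in (1, 2):
            top = ordination.top_loading_genes(pca, pc, config.top_n)
            tdf = pd.DataFrame(top, columns=["gene", "loading"])
            data_io.write_table(tdf, outdir / f"top_genes_pc{pc}.tsv", params=hdr)
        return pca

    pca = _pca()
    report["pc1_variance_pct"] = round(100 * float(pca.variance_explained[0]), 2)
    report["pc2_variance_pct"] = round(100 * float(pca.variance_explained[1]), 2)

    # ---- motif ----
    @_stage("motif")
    def _motif():
        records, planted = synthetic_data.simulate_promoters(
            filtered.gene_ids,
            motif=config.motif,
            planted_fraction=config.planted_motif_fraction,
            length=config.promoter_length,
            gc=config.promoter_gc,
            seed=config.seed,
        )
        SeqIO.write(records, str(outdir / "promoters.fasta"), "fasta")
        hits = motif_scan.scan_consensus(records, config.motif)
        universe = set(filtered.gene_ids)
        upreg = set(de.loc[de["de"] & (de["log2fc"] > 0), "gene"]) & universe
        k_up, p_up = motif_scan.motif_enrichment(hits, upreg, universe)
        core_up = {
            r.gene for r in core.members.itertuples(index=False) if r.direction == "up"
        } & universe
        k_core, p_core = motif_scan.motif_enrichment(hits, core_up, universe)
        hits_df = pd.DataFrame(
            [
                {"gene": g, "n_hits": len(pos), "positions": ";".join(f"{i}{s}" for i, s in pos)}
                for g, pos in hits.positions.items()
            ]
        )
        data_io.write_table(hits_df, outdir / "motif_hits.tsv", params=hdr)
        enr_df = pd.DataFrame(
            [
                {"target": "upregulated", "n_target": len(upreg), "overlap": k_up, "p": p_up},
                {"target": "core_up", "n_target": len(core_up), "overlap": k_core, "p": p_core},
            ]
        )
        data_io.write_table(enr_df, outdir / "motif_enrichment.tsv", params=hdr)
        return hits, (k_up, p_up), (k_core, p_core)

    hits, (k_up, p_up), (k_core, p_core) = _motif()
    report["motif_genes_upregulated"] = k_up
    report["motif_genes_core_up"] = k_core

    report_df = pd.DataFrame(
        [{"metric": k, "value": v} for k, v in report.items()]
    )
    data_io.write_table(report_df, outdir / "report.tsv", params=hdr)
    return report
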