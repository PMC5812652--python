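"""Simulation benchmarks: statistical validity, power, and planted-structure
recovery of the full pipeline.

These routines generate seeded synthetic experiments with known truth, run
the package's own analysis path on them, and score the results. They back
both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import kstest

from . import de_engine, kinetics, motif_scan, normalization, response_sets
from . import synthetic_data
from .data_io import build_design

__all__ = [
    "null_calibration",
    "power_and_dispersion",
    "pipeline_recovery",
    "motif_benchmark",
]


def null_calibration(n_genes: int = 4000, phi: float = 0.2, seed: int = 0) -> dict:
    """Global-null two-group experiment (3 vs 9 samples): p-value uniformity
    (KS statistic) and the fraction of genes flagged at FDR 0.05."""
    counts, samples, _ = synthetic_data.simulate_two_group(
        n_genes, 3, 9, lib_size=1e6, phi=phi, seed=seed
    )
    design = build_design(counts, samples)
    filtered = normalization.filter_low_counts(counts, 1.2, design.smallest_group_size())
    factors = normalization.tmm_factors(filtered)
    disp = de_engine.estimate_dispersion(filtered, design, factors)
    de = de_engine.run_all_contrasts(filtered, design, factors, disp)
    return {
        "ks_D": float(kstest(de["p"], "uniform").statistic),
        "flagged_fraction": float(de["de"].mean()),
        "n": filtered.n_genes,
    }


def power_and_dispersion(
    n_genes: int = 2000,
    phi: float = 0.2,
    lfc: float = 2.0,
    frac_de: float = 0.1,
    lib_size: float = 5e6,
    seed: int = 0,
) -> dict:
    """Planted-effect two-group experiment (3 vs 9, |log2FC| = 2, depth 5M):
    DE sensitivity at FDR 0.05 and recovery of the true dispersion."""
    counts, samples, planted = synthetic_data.simulate_two_group(
        n_genes, 3, 9, lib_size=lib_size, phi=phi,
        lfc_magnitude=lfc, frac_de=frac_de, seed=seed,
    )
    design = build_design(counts, samples)
    filtered = normalization.filter_low_counts(counts, 1.2, design.smallest_group_size())
    factors = normalization.tmm_factors(filtered)
    disp = de_engine.estimate_dispersion(filtered, design, factors)
    de = de_engine.run_all_contrasts(filtered, design, factors, disp)
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    kept_planted = [g for g in filtered.gene_ids if planted[gene_pos[g]] != 0]
    flagged = set(de.loc[de["de"], "gene"])
    sensitivity = (
        sum(1 for g in kept_planted if g in flagged) / len(kept_planted)
        if kept_planted
        else float("nan")
    )
    return {
        "sensitivity": float(sensitivity),
        "phi_median": float(disp.phi_median),
        "phi_true": phi,
        "n": filtered.n_genes,
        "n_planted": len(kept_planted),
    }


def pipeline_recovery(seed: int = 0, n_genes: int = 2000) -> dict:
    """Run the default multi-condition simulation through the full analysis
    and score every stage against the planted truth."""
    cfg = synthetic_data.SimConfig(n_genes=n_genes, seed=seed)
    counts, samples, truth = synthetic_data.simulate_experiment(cfg)
    design = build_design(counts, samples)
    filtered = normalization.filter_low_counts(counts, 1.2, design.smallest_group_size())
    factors = normalization.tmm_factors(filtered)
    disp = de_engine.estimate_dispersion(filtered, design, factors)
    de = de_engine.run_all_contrasts(filtered, design, factors, disp)
    live = design.live_conditions()
    kept = set(filtered.gene_ids)

    support = response_sets.condition_support(de, live)
    core7 = response_sets.define_core(support, 7)
    planted_core = (
        set(truth.genes_of_class("core_up")) | set(truth.genes_of_class("core_down"))
    ) & kept
    called = core7.genes
    core_sensitivity = (
        len(called & planted_core) / len(planted_core) if planted_core else float("nan")
    )
    false_core_fraction = len(called - planted_core) / len(called) if called else 0.0

    nesting = (
        response_sets.define_core(support, 8).genes
        <= called
        <= response_sets.define_core(support, 6).genes
    )

    # unique-gene assignment: planted unique gene recovered iff assigned to
    # exactly its planted bacterium
    uniq = response_sets.unique_genes(de, live)
    assigned: dict[str, str] = {}
    for r in uniq.itertuples(index=False):
        for g in r.unique_genes.split(",") if r.unique_genes else []:
            assigned[g] = r.bacterium
    tg = truth.genes.set_index("gene")
    planted_unique = [
        g for g in truth.genes_of_class("unique_per_bacterium") if g in kept
    ]
    unique_sensitivity = (
        sum(1 for g in planted_unique if assigned.get(g) == tg.loc[g, "bacteria"])
        / len(planted_unique)
        if planted_unique
        else float("nan")
    )

    # trajectory accuracy per planted class over responding full-course cells
    conds3 = design.three_timepoint_conditions()
    calls = kinetics.classify_all(de, conds3)
    call_label = calls.set_index(["gene", "condition"])["label"]
    traj_acc = {}
    for klass in ("recovered", "plateau", "continued"):
        total = correct = 0
        planted_rows = tg[
            (tg["trajectory"] == klass)
            & tg["class"].isin(["core_up", "core_down", "unique_per_bacterium"])
        ]
        for g, row in planted_rows.iterrows():
            if g not in kept:
                continue
            for b in row["bacteria"].split(",") if row["bacteria"] else []:
                if b not in conds3 or (g, b) not in call_label.index:
                    continue
                total += 1
                correct += call_label[(g, b)] == klass
        traj_acc[klass] = {
            "accuracy": correct / total if total else float("nan"),
            "n": total,
        }

    rec = kinetics.recovery_fractions(calls)
    mean_recovery = float(rec["pct_recovered"].mean())

    return {
        "core_sensitivity": float(core_sensitivity),
        "false_core_fraction": float(false_core_fraction),
        "core_size": len(called),
        "n_planted_core": len(planted_core),
        "nesting_holds": bool(nesting),
        "unique_sensitivity": float(unique_sensitivity),
        "n_planted_unique": len(planted_unique),
        "trajectory": traj_acc,
        "mean_recovery_pct": mean_recovery,
        "n_genes": filtered.n_genes,
    }


def motif_benchmark(
    n_promoters: int = 500,
    length: int = 4000,
    planted_fraction: float = 0.2,
    gc: float = 0.43,
    motif: str = "TGCCACGT",
    seed: int = 0,
) -> dict:
    """Planted-motif promoter set: detection of every planted promoter,
    background hit count vs the closed-form expectation, and hypergeometric
    enrichment of the planted set."""
    gene_ids = [f"g{i:04d}" for i in range(n_promoters)]
    records, planted = synthetic_data.simulate_promoters(
        gene_ids, motif=motif, planted_fraction=planted_fraction,
        length=length, gc=gc, seed=seed,
    )
    hits = motif_scan.scan_consensus(records, motif)
    detected = hits.genes_with_hits()
    planted_detected = len(planted & detected) / len(planted) if planted else float("nan")

    bg_records, _ = synthetic_data.simulate_promoters(
        gene_ids, motif=motif, planted_fraction=0.0, length=length, gc=gc,
        seed=seed + 1,
    )
    bg_hits = motif_scan.scan_consensus(bg_records, motif)
    expected = n_promoters * motif_scan.expected_background_hits(length, motif, gc)
    z = (bg_hits.total_hits() - expected) / math.sqrt(expected)

    k, p = motif_scan.motif_enrichment(hits, planted, set(gene_ids))
    return {
        "planted_detected_fraction": float(planted_detected),
        "background_hits": bg_hits.total_hits(),
        "background_expected": float(expected),
        "background_z": float(z),
        "enrichment_overlap": k,
        "enrichment_p": float(p),
        "n": n_promoters,
    }
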