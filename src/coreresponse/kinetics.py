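"""Time-course trajectory classification and recovery accounting.

For each gene x infection with the full 12/36/132 h series, the late fold
change is compared to the early peak: a gene that was DE at 12 and/or 36 h
but is no longer DE at 132 h has *recovered*; otherwise the recovery ratio
r = log2FC(132 h) / peak log2FC classifies it as *continued* (r >= 1.25),
*plateau* (0.75 <= r < 1.25) or *partial* (r < 0.75, still DE late). The
peak is the 12/36 h log2FC of largest magnitude in the gene's overall
direction (max for upregulated genes, min for downregulated). Genes
significantly induced at one early timepoint and significantly repressed at
the other are excluded as sign-flips; genes never DE are nonresponsive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryCall",
    "classify_path",
    "classify_all",
    "recovery_fraction",
    "recovery_fractions",
    "trajectory_table",
]

LABELS = (
    "recovered",
    "plateau",
    "continued",
    "partial",
    "excluded_signflip",
    "nonresponsive",
)


@dataclass
class TrajectoryCall:
    gene: str
    condition: str
    responsive_early: bool
    de_132: bool
    peak_lfc: float
    lfc_132: float
    recovery_ratio: float  # NaN when undefined
    label: str


def classify_path(
    rows: pd.DataFrame,
    theta_plat: float = 0.75,
    theta_cont: float = 1.25,
    timepoints: tuple[float, float, float] = (12.0, 36.0, 132.0),
) -> TrajectoryCall:
    """Classify one gene x condition from its DE-table rows at the three
    timepoints."""
    t_early1, t_early2, t_late = timepoints
    by_tp = {float(r.timepoint_h): r for r in rows.itertuples(index=False)}
    for tp in timepoints:
        if tp not in by_tp:
            raise ValueError(
                f"missing timepoint {tp} h for gene "
                f"{rows['gene'].iloc[0]!r}, condition {rows['condition'].iloc[0]!r}"
            )
    r1, r2, rl = by_tp[t_early1], by_tp[t_early2], by_tp[t_late]
    gene = r1.gene
    condition = r1.condition
    responsive_early = bool(r1.de or r2.de)
    de_132 = bool(rl.de)
    lfc_132 = float(rl.log2fc)

    def call(peak, ratio, label):
        return TrajectoryCall(
            gene=gene,
            condition=condition,
            responsive_early=responsive_early,
            de_132=de_132,
            peak_lfc=peak,
            lfc_132=lfc_132,
            recovery_ratio=ratio,
            label=label,
        )

    # sign-flip: significant in opposite directions at the two early points
    if r1.de and r2.de and np.sign(r1.log2fc) * np.sign(r2.log2fc) < 0:
        return call(float("nan"), float("nan"), "excluded_signflip")
    if not responsive_early and not de_132:
        return call(float("nan"), float("nan"), "nonresponsive")
    if responsive_early and not de_132:
        return call(float("nan"), float("nan"), "recovered")

    # still DE late: compute the degree of recovery
    if responsive_early:
        # overall direction from the early DE call with the larger |log2FC|
        cands = [r for r in (r1, r2) if r.de]
        lead = max(cands, key=lambda r: abs(r.log2fc))
        up = lead.log2fc >= 0
    else:
        # DE only at 132 h: no early peak to recover from; by convention the
        # gene is still departing from baseline late, i.e. "continued"
        return call(float("nan"), float("nan"), "continued")
    peak = max(r1.log2fc, r2.log2fc) if up else min(r1.log2fc, r2.log2fc)
    if peak == 0:
        return call(0.0, float("nan"), "continued")
    ratio = lfc_132 / peak
    if ratio >= theta_cont:
        label = "continued"
    elif ratio >= theta_plat:
        label = "plateau"
    else:
        label = "partial"
    return call(float(peak), float(ratio), label)


def classify_all(
    de: pd.DataFrame,
    conditions: list[str],
    theta_plat: float = 0.75,
    theta_cont: float = 1.25,
    timepoints: tuple[float, float, float] = (12.0, 36.0, 132.0),
) -> pd.DataFrame:
    """Trajectory calls for every gene under every full-time-course condition."""
    calls = []
    sub = de[de["condition"].isin(conditions)]
    for (gene, cond), rows in sub.groupby(["gene", "condition"], sort=False):
        tc = classify_path(rows, theta_plat, theta_cont, timepoints)
        calls.append(
            {
                "gene": gene,
                "condition": cond,
                "responsive_early": tc.responsive_early,
                "de_132": tc.de_132,
                "peak_lfc": tc.peak_lfc,
                "lfc_132": tc.lfc_132,
                "recovery_ratio": tc.recovery_ratio,
                "label": tc.label,
            }
        )
    return pd.DataFrame(calls)


def recovery_fraction(calls: pd.DataFrame) -> float | None:
    """Percentage of early-responsive (non-sign-flip) genes that recovered."""
    eligible = calls[calls["responsive_early"] & (calls["label"] != "excluded_signflip")]
    if len(eligible) == 0:
        return None
    return 100.0 * float((eligible["label"] == "recovered").sum()) / len(eligible)


def recovery_fractions(calls: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cond, sub in calls.groupby("condition", sort=False):
        frac = recovery_fraction(sub)
        rows.append(
            {
                "condition": cond,
                "pct_recovered": float("nan") if frac is None else frac,
                "n_responsive": int(
                    (sub["responsive_early"] & (sub["label"] != "excluded_signflip")).sum()
                ),
            }
        )
    return pd.DataFrame(rows)


def trajectory_table(calls: pd.DataFrame, core_genes: set[str]) -> pd.DataFrame:
    """Core genes x conditions matrix of trajectory labels ('nonresponsive'
    where the gene was not DE under that condition)."""
    sub = calls[calls["gene"].isin(core_genes)]
    if len(sub) == 0:
        return pd.DataFrame()
    return sub.pivot(index="gene", columns="condition", values="label").fillna(
        "nonresponsive"
    )
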