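"""Set-defining procedures over the DE table.

The core response is the set of genes differentially expressed in response to
at least ``cutoff`` (default 7) of the live bacteria at one or more
timepoints. Unique genes respond to exactly one bacterium across all
timepoints. The Gram/PGN partition splits responding genes by whether their
supporting bacteria are all Lys-type (Gram-positive), all DAP-type
(Gram-negative), or mixed. Control overlaps intersect the core with the
sterile-wound and heat-killed response sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SupportTable",
    "CoreSet",
    "condition_support",
    "define_core",
    "cutoff_sweep",
    "unique_genes",
    "gram_partition",
    "overlap_report",
    "de_gene_set",
    "pathway_regulation_annotation",
]


@dataclass
class SupportTable:
    """Per-gene DE support across live bacteria.

    ``table`` columns: gene, support (comma-joined bacteria), s (support
    count), directions (comma-joined per-bacterium signs aligned with
    support). The universe of bacteria is recorded so cutoffs can be
    validated.
    """

    table: pd.DataFrame
    bacteria: list[str]

    def support_sets(self) -> dict[str, set[str]]:
        return {
            r.gene: set(r.support.split(",")) if r.support else set()
            for r in self.table.itertuples(index=False)
        }

    def direction_map(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for r in self.table.itertuples(index=False):
            bs = r.support.split(",") if r.support else []
            ds = r.directions.split(",") if r.directions else []
            out[r.gene] = dict(zip(bs, ds))
        return out


@dataclass
class CoreSet:
    cutoff: int
    members: pd.DataFrame  # gene, s, direction in {up, down, discordant}

    @property
    def genes(self) -> set[str]:
        return set(self.members["gene"])

    def count(self, direction: str) -> int:
        return int((self.members["direction"] == direction).sum())


def condition_support(de: pd.DataFrame, live_conditions: list[str]) -> SupportTable:
    """Bacterium b supports gene g iff g is DE for (b, t) at any timepoint t.

    The per-bacterium direction is the sign of log2FC at the timepoint with
    the smallest q (ties broken by earliest timepoint).
    """
    live = de[de["condition"].isin(live_conditions)]
    genes = list(dict.fromkeys(de["gene"]))
    rows = []
    flagged = live[live["de"]]
    # smallest q, then earliest timepoint, per (gene, bacterium)
    best = (
        flagged.sort_values(["q", "timepoint_h"], kind="stable")
        .groupby(["gene", "condition"], sort=False)
        .first()
        .reset_index()
    )
    support_map: dict[str, list[tuple[str, str]]] = {}
    for r in best.itertuples(index=False):
        d = "up" if r.log2fc >= 0 else "down"
        support_map.setdefault(r.gene, []).append((r.condition, d))
    order = {b: i for i, b in enumerate(live_conditions)}
    for g in genes:
        entries = sorted(support_map.get(g, []), key=lambda e: order[e[0]])
        rows.append(
            {
                "gene": g,
                "support": ",".join(b for b, _ in entries),
                "s": len(entries),
                "directions": ",".join(d for _, d in entries),
            }
        )
    return SupportTable(table=pd.DataFrame(rows), bacteria=list(live_conditions))


def define_core(support: SupportTable, cutoff: int = 7) -> CoreSet:
    """Core = genes supported by >= cutoff bacteria.

    Direction is 'up'/'down' when a strict majority (>= ceil((s+1)/2)) of the
    supporting bacteria agree in sign, else 'discordant'.
    """
    if not 1 <= cutoff <= len(support.bacteria):
        raise ValueError(
            f"cutoff {cutoff} out of range [1, {len(support.bacteria)}]"
        )
    rows = []
    for r in support.table.itertuples(index=False):
        if r.s < cutoff:
            continue
        ds = r.directions.split(",") if r.directions else []
        n_up = ds.count("up")
        n_down = ds.count("down")
        need = math.ceil((r.s + 1) / 2)
        if n_up >= need:
            direction = "up"
        elif n_down >= need:
            direction = "down"
        else:
            direction = "discordant"
        rows.append({"gene": r.gene, "s": r.s, "direction": direction})
    members = pd.DataFrame(rows, columns=["gene", "s", "direction"])
    return CoreSet(cutoff=cutoff, members=members)


def cutoff_sweep(
    support: SupportTable, cutoffs: list[int] | None = None
) -> pd.DataFrame:
    """Core-set sizes by direction across inclusion cutoffs."""
    if cutoffs is None:
        cutoffs = list(range(6, len(support.bacteria) + 1))
    rows = []
    for c in cutoffs:
        core = define_core(support, c)
        rows.append(
            {
                "cutoff": c,
                "n_up": core.count("up"),
                "n_down": core.count("down"),
                "n_discordant": core.count("discordant"),
                "n_total": len(core.members),
            }
        )
    return pd.DataFrame(rows)


def unique_genes(de: pd.DataFrame, live_conditions: list[str]) -> pd.DataFrame:
    """Genes DE in exactly one live infection across all timepoints.

    Returns per-bacterium rows: n_de (genes DE for that bacterium at any
    timepoint), n_unique, pct_unique, and the unique gene list.
    """
    support = condition_support(de, live_conditions)
    sets = support.support_sets()
    per_b_de: dict[str, set[str]] = {b: set() for b in live_conditions}
    per_b_unique: dict[str, set[str]] = {b: set() for b in live_conditions}
    for g, s in sets.items():
        for b in s:
            per_b_de[b].add(g)
        if len(s) == 1:
            per_b_unique[next(iter(s))].add(g)
    rows = []
    for b in live_conditions:
        n_de = len(per_b_de[b])
        n_u = len(per_b_unique[b])
        rows.append(
            {
                "bacterium": b,
                "n_de": n_de,
                "n_unique": n_u,
                "pct_unique": 100.0 * n_u / n_de if n_de else float("nan"),
                "unique_genes": ",".join(sorted(per_b_unique[b])),
            }
        )
    return pd.DataFrame(rows)


def gram_partition(support: SupportTable, pgn_map: dict[str, str]) -> dict:
    """Partition responding genes (s >= 1) by the PGN type of their
    supporting bacteria, plus the stricter all-members consistent-direction
    sets per Gram class."""
    for b in support.bacteria:
        if b not in pgn_map or pgn_map[b] not in ("Lys", "DAP"):
            raise ValueError(f"bacterium {b!r} lacks a Lys/DAP PGN label")
    lys = {b for b in support.bacteria if pgn_map[b] == "Lys"}
    dap = {b for b in support.bacteria if pgn_map[b] == "DAP"}
    sets = support.support_sets()
    dirs = support.direction_map()
    lys_only, dap_only, both = set(), set(), set()
    for g, s in sets.items():
        if not s:
            continue
        if s <= lys:
            lys_only.add(g)
        elif s <= dap:
            dap_only.add(g)
        else:
            both.add(g)

    def all_members(cls: set[str], want: str) -> set[str]:
        out = set()
        for g, s in sets.items():
            if cls <= s and all(dirs[g][b] == want for b in cls):
                out.add(g)
        return out

    return {
        "lys_only": lys_only,
        "dap_only": dap_only,
        "both": both,
        # within the exclusive sets: regulated by every member of the class,
        # in a consistent direction, and by no bacterium of the other class
        "lys_all_up": all_members(lys, "up") & lys_only,
        "lys_all_down": all_members(lys, "down") & lys_only,
        "dap_all_up": all_members(dap, "up") & dap_only,
        "dap_all_down": all_members(dap, "down") & dap_only,
    }


def de_gene_set(de: pd.DataFrame, conditions: list[str]) -> set[str]:
    """Genes DE at any timepoint in any of the given conditions."""
    sub = de[de["condition"].isin(conditions) & de["de"]]
    return set(sub["gene"])


def overlap_report(
    core: set[str],
    wound_set: set[str],
    hk_set: set[str],
    universe: set[str],
    external: set[str] | None = None,
) -> dict[str, int]:
    """All 7 Venn cells for (core, wound, heat-killed), plus overlaps with an
    optional external gene list (e.g. a previously published
    infection-response set)."""
    for name, s in (("core", core), ("wound", wound_set), ("heat_killed", hk_set)):
        stray = s - universe
        if stray:
            warnings.warn(
                f"{name} set contains {len(stray)} gene(s) outside the universe: "
                f"{sorted(stray)[:5]}..."
            )
    c, w, h = core & universe, wound_set & universe, hk_set & universe
    report = {
        "core_only": len(c - w - h),
        "wound_only": len(w - c - h),
        "hk_only": len(h - c - w),
        "core_wound_only": len((c & w) - h),
        "core_hk_only": len((c & h) - w),
        "wound_hk_only": len((w & h) - c),
        "core_wound_hk": len(c & w & h),
    }
    if external is not None:
        stray = external - universe
        if stray:
            warnings.warn(
                f"external list contains {len(stray)} gene(s) outside the universe"
            )
        e = external & universe
        report.update(
            {
                "external_total": len(e),
                "external_core": len(e & c),
                "external_wound": len(e & w),
                "external_hk": len(e & h),
            }
        )
    return report


def pathway_regulation_annotation(
    wt_expr: np.ndarray, mutant_expr: np.ndarray, threshold: float = 0.20
) -> pd.DataFrame:
    """Flag genes whose expression changes by >= ``threshold`` (relative to
    wildtype) in a pathway-mutant background; genes with non-positive
    wildtype levels are unevaluable."""
    wt = np.asarray(wt_expr, dtype=float)
    mut = np.asarray(mutant_expr, dtype=float)
    if wt.shape != mut.shape:
        raise ValueError("wildtype and mutant vectors differ in length")
    evaluable = wt > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(mut - wt) / wt
    regulated = evaluable & (rel >= threshold)
    return pd.DataFrame(
        {"regulated": regulated, "evaluable": evaluable, "relative_change": rel}
    )
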