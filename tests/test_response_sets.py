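import numpy as np
import pandas as pd
import pytest

from coreresponse.response_sets import (
    SupportTable,
    condition_support,
    cutoff_sweep,
    de_gene_set,
    define_core,
    gram_partition,
    overlap_report,
    pathway_regulation_annotation,
    unique_genes,
)

BACTERIA = ["Ml", "Ef", "Sa", "Ec", "Sm", "Ecc15", "Pr", "Ps", "Db11", "Pe"]
PGN = {b: ("Lys" if b in ("Ml", "Ef", "Sa") else "DAP") for b in BACTERIA}


def _random_de_table(seed, n_genes=30, conditions=None, timepoints=(12.0, 36.0)):
    conditions = conditions or BACTERIA[:4] + ["EfHK"]
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        for c in conditions:
            for t in timepoints:
                de = bool(rng.random() < 0.3)
                rows.append(
                    {
                        "gene": f"g{g}",
                        "condition": c,
                        "timepoint_h": t,
                        "log2fc": float(rng.normal()),
                        "p": float(rng.random()),
                        "q": float(rng.random()),
                        "de": de,
                        "direction": "none",
                    }
                )
    return pd.DataFrame(rows)


def _support_from(entries, bacteria=BACTERIA):
    """entries: {gene: [(bacterium, direction), ...]}"""
    rows = [
        {
            "gene": g,
            "support": ",".join(b for b, _ in e),
            "s": len(e),
            "directions": ",".join(d for _, d in e),
        }
        for g, e in entries.items()
    ]
    return SupportTable(table=pd.DataFrame(rows), bacteria=list(bacteria))


class TestSupport:
    def test_any_timepoint_counts_and_live_only(self):
        rows = []
        for cond, tp, de in [("Pr", 12.0, False), ("Pr", 36.0, True), ("EfHK", 12.0, True)]:
            rows.append(
                {"gene": "gX", "condition": cond, "timepoint_h": tp,
                 "log2fc": 1.0, "p": 0.01, "q": 0.01, "de": de, "direction": "up"}
            )
        de = pd.DataFrame(rows)
        sup = condition_support(de, ["Pr", "Ec"])
        row = sup.table.iloc[0]
        assert row["support"] == "Pr" and row["s"] == 1  # heat-killed ignored

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_any_over_time(self, seed):
        de = _random_de_table(seed)
        live = BACTERIA[:4]
        sup = condition_support(de, live)
        sets = sup.support_sets()
        for g in de["gene"].unique():
            expected = {
                b
                for b in live
                if de[(de["gene"] == g) & (de["condition"] == b) & de["de"]].shape[0] > 0
            }
            assert sets[g] == expected

    def test_direction_from_smallest_q_then_earliest(self):
        rows = [
            {"gene": "g", "condition": "Pr", "timepoint_h": 36.0,
             "log2fc": -2.0, "p": 0.001, "q": 0.001, "de": True, "direction": "down"},
            {"gene": "g", "condition": "Pr", "timepoint_h": 12.0,
             "log2fc": 2.0, "p": 0.02, "q": 0.02, "de": True, "direction": "up"},
            {"gene": "g", "condition": "Ec", "timepoint_h": 12.0,
             "log2fc": 1.0, "p": 0.01, "q": 0.01, "de": True, "direction": "up"},
            {"gene": "g", "condition": "Ec", "timepoint_h": 36.0,
             "log2fc": -1.0, "p": 0.01, "q": 0.01, "de": True, "direction": "down"},
        ]
        sup = condition_support(pd.DataFrame(rows), ["Pr", "Ec"])
        dirs = sup.direction_map()["g"]
        assert dirs["Pr"] == "down"  # smallest q wins
        assert dirs["Ec"] == "up"  # tie -> earliest timepoint


class TestCore:
    def test_membership_and_direction_rules(self):
        sup = _support_from(
            {
                "all_up": [(b, "up") for b in BACTERIA[:7]],
                "six": [(b, "up") for b in BACTERIA[:6]],
                "split": [(b, "up") for b in BACTERIA[:4]]
                + [(b, "down") for b in BACTERIA[4:8]],
            }
        )
        core = define_core(sup, 7)
        members = core.members.set_index("gene")
        assert "all_up" in members.index and members.loc["all_up", "direction"] == "up"
        assert "six" not in members.index
        assert members.loc["split", "direction"] == "discordant"

    def test_cutoff_validation(self):
        sup = _support_from({"g": [("Ml", "up")]})
        with pytest.raises(ValueError):
            define_core(sup, 0)
        with pytest.raises(ValueError):
            define_core(sup, 11)

    def test_sweep_monotone_and_nesting(self, small_experiment):
        de = small_experiment["de"]
        live = small_experiment["design"].live_conditions()
        sup = condition_support(de, live)
        sweep = cutoff_sweep(sup, list(range(1, 11)))
        totals = sweep["n_total"].to_numpy()
        assert np.all(np.diff(totals) <= 0)
        g6, g7, g8 = (define_core(sup, c).genes for c in (6, 7, 8))
        assert g8 <= g7 <= g6

    def test_cutoff_one_is_all_responding(self):
        sup = _support_from({"a": [("Ml", "up")], "b": [], "c": [("Ec", "down"), ("Pr", "down")]})
        core = define_core(sup, 1)
        assert core.genes == {"a", "c"}


class TestUnique:
    def test_definition_and_percentages_match_brute_force(self):
        de = _random_de_table(7, n_genes=40, conditions=BACTERIA[:5])
        live = BACTERIA[:5]
        out = unique_genes(de, live).set_index("bacterium")
        sup = condition_support(de, live).support_sets()
        for b in live:
            expected_unique = {g for g, s in sup.items() if s == {b}}
            expected_de = {g for g, s in sup.items() if b in s}
            assert set(
                out.loc[b, "unique_genes"].split(",") if out.loc[b, "unique_genes"] else []
            ) == expected_unique
            assert out.loc[b, "n_de"] == len(expected_de)
            if expected_de:
                assert out.loc[b, "pct_unique"] == pytest.approx(
                    100 * len(expected_unique) / len(expected_de)
                )

    def test_multi_bacterium_gene_not_unique(self):
        rows = [
            {"gene": "g", "condition": c, "timepoint_h": 12.0, "log2fc": 1.0,
             "p": 0.01, "q": 0.01, "de": True, "direction": "up"}
            for c in ("Sa", "Pe")
        ]
        out = unique_genes(pd.DataFrame(rows), ["Sa", "Pe"])
        assert out["n_unique"].sum() == 0


class TestGramPartition:
    def test_class_assignment(self):
        sup = _support_from(
            {
                "lysg": [("Ml", "up"), ("Ef", "up")],
                "dapg": [("Ec", "down")],
                "bothg": [("Ec", "up"), ("Ml", "up")],
                "none": [],
            }
        )
        part = gram_partition(sup, PGN)
        assert part["lys_only"] == {"lysg"}
        assert part["dap_only"] == {"dapg"}
        assert part["both"] == {"bothg"}

    def test_all_members_consistent_direction(self):
        lys = ["Ml", "Ef", "Sa"]
        sup = _support_from(
            {
                "allup": [(b, "up") for b in lys],
                "mixed": [("Ml", "up"), ("Ef", "down"), ("Sa", "up")],
                "partial": [("Ml", "up"), ("Ef", "up")],
                "leaky": [(b, "up") for b in lys] + [("Ec", "up")],
            }
        )
        part = gram_partition(sup, PGN)
        assert part["lys_all_up"] == {"allup"}  # leaky is in 'both', not exclusive

    def test_unlabeled_bacterium_rejected(self):
        sup = _support_from({"g": [("Ml", "up")]})
        bad = dict(PGN)
        bad["Pe"] = "none"
        with pytest.raises(ValueError, match="Pe"):
            gram_partition(sup, bad)


class TestOverlap:
    def test_disjoint_and_subset_cases(self):
        uni = {f"g{i}" for i in range(10)}
        rep = overlap_report({"g0"}, {"g1"}, {"g2"}, uni)
        assert rep["core_wound_hk"] == 0 and rep["core_only"] == 1
        rep2 = overlap_report({"g0", "g1"}, set(), {"g0", "g1", "g2"}, uni)
        assert rep2["core_only"] == 0 and rep2["core_hk_only"] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_cells_match_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        uni = {f"g{i}" for i in range(50)}
        pick = lambda: {g for g in uni if rng.random() < 0.4}
        c, w, h = pick(), pick(), pick()
        rep = overlap_report(c, w, h, uni)
        assert rep["core_wound_hk"] == len(c & w & h)
        assert rep["wound_only"] == len(w - c - h)
        assert sum(rep.values()) == len(c | w | h)

    def test_external_and_stray_warning(self):
        uni = {"a", "b"}
        with pytest.warns(UserWarning, match="outside the universe"):
            rep = overlap_report({"a", "zz"}, set(), set(), uni, external={"a"})
        assert rep["external_core"] == 1


class TestPathwayAnnotation:
    def test_twenty_percent_rule(self):
        out = pathway_regulation_annotation(
            np.array([100.0, 100.0, 100.0, 0.0]),
            np.array([80.0, 81.0, 120.0, 5.0]),
        )
        assert list(out["regulated"]) == [True, False, True, False]
        assert list(out["evaluable"]) == [True, True, True, False]


def test_de_gene_set(small_experiment):
    de = small_experiment["de"]
    live = small_experiment["design"].live_conditions()
    genes = de_gene_set(de, live)
    assert genes == set(de[de["condition"].isin(live) & de["de"]]["gene"])
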