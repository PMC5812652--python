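"""Seeded negative-binomial count simulator with planted structure.

The default configuration mirrors a systemic-infection RNA-seq experiment in
adult *Drosophila melanogaster*: 10 live bacteria (3 with Lys-type and 7 with
DAP-type peptidoglycan; the 4 high-virulence species sampled at 12 h only
because they kill their hosts before later timepoints), an unchallenged
control (UC) collapsed across timepoints, a sterile-wound control (SW), two
heat-killed inocula (EfHK, PrHK), timepoints 12/36/132 h, and 3 replicates
per condition x timepoint.

Genes are planted in known classes (core up/down, unique to one bacterium,
wound-responsive, heat-killed-responsive, sign-flipping, null) with known
log2 fold changes and time-course trajectories, so every downstream stage of
the pipeline can be scored against ground truth.

Counts are drawn NB(mean = lib_size_k * p_gk, dispersion phi_g) with
variance mu + phi*mu^2. Planted fold changes act on the expected proportions
p_gk before depth scaling, so library-size variation is orthogonal to the
planted effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data_io import CountMatrix, SampleRecord

__all__ = [
    "ConditionSpec",
    "SimConfig",
    "TruthTable",
    "default_conditions",
    "simulate_experiment",
    "simulate_two_group",
    "simulate_promoters",
    "TRAJECTORY_SCALES",
    "IUPAC_CODES",
]

# time-course scaling of the planted log2FC at (12, 36, 132) h
TRAJECTORY_SCALES = {
    "recovered": (1.0, 0.5, 0.0),
    "plateau": (1.0, 1.0, 1.0),
    "continued": (1.0, 1.5, 2.0),
}

GENE_CLASSES = (
    "core_up",
    "core_down",
    "unique_per_bacterium",
    "wound_responsive",
    "hk_responsive",
    "signflip",
    "null",
)


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    challenge_type: str
    pgn_type: str
    virulence: str
    timepoints: tuple[float, ...]
    replicates: int = 3


def default_conditions() -> list[ConditionSpec]:
    """The 10-bacterium panel plus controls.

    Lys-type (Gram-positive): Ml (low), Ef (intermediate), Sa (high).
    DAP-type (Gram-negative): Ec, Sm (low); Ecc15, Pr (intermediate);
    Ps, Db11, Pe (high). High-virulence species are sampled at 12 h only.
    """
    full = (12.0, 36.0, 132.0)
    early = (12.0,)
    bacteria = [
        ("Ml", "Lys", "low"),
        ("Ef", "Lys", "intermediate"),
        ("Sa", "Lys", "high"),
        ("Ec", "DAP", "low"),
        ("Sm", "DAP", "low"),
        ("Ecc15", "DAP", "intermediate"),
        ("Pr", "DAP", "intermediate"),
        ("Ps", "DAP", "high"),
        ("Db11", "DAP", "high"),
        ("Pe", "DAP", "high"),
    ]
    conds = [
        ConditionSpec(name, "live", pgn, vir, early if vir == "high" else full)
        for name, pgn, vir in bacteria
    ]
    conds.append(ConditionSpec("UC", "unchallenged", "none", "none", full))
    conds.append(ConditionSpec("SW", "sterile_wound", "none", "none", full))
    conds.append(ConditionSpec("EfHK", "heat_killed", "Lys", "none", full))
    conds.append(ConditionSpec("PrHK", "heat_killed", "DAP", "none", full))
    return conds


@dataclass
class SimConfig:
    """Study conditions for the simulator (defaults are the package's chosen
    conditions; see docs/methods.md for rationale)."""

    n_genes: int = 2000
    conditions: list[ConditionSpec] = field(default_factory=default_conditions)
    lib_size_mean: float = 2_000_000.0
    lib_size_cv: float = 0.1
    baseline_logmean_mu: float = 0.0
    baseline_logmean_sigma: float = 1.0
    dispersion_phi0: float = 0.01
    dispersion_slope: float = 2.0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "core_up": 0.06,
            "core_down": 0.03,
            "unique_per_bacterium": 0.10,
            "wound_responsive": 0.02,
            "hk_responsive": 0.02,
            "signflip": 0.01,
        }
    )
    core_support: int = 8
    lfc_magnitude: float = 2.0
    trajectory_mix: dict[str, float] = field(
        default_factory=lambda: {"recovered": 0.5, "plateau": 0.25, "continued": 0.25}
    )
    signflip_n_bacteria: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.class_fractions) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        fracs = list(self.class_fractions.values())
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class fractions must be in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError("class fractions sum to more than 1")
        if self.dispersion_phi0 <= 0:
            raise ValueError("dispersion_phi0 must be > 0")
        mix = sum(self.trajectory_mix.values())
        if not math.isclose(mix, 1.0, rel_tol=1e-9):
            raise ValueError("trajectory_mix must sum to 1")
        live = [c for c in self.conditions if c.challenge_type == "live"]
        if live and not 1 <= self.core_support <= len(live):
            raise ValueError("core_support out of range for the bacterial panel")


@dataclass
class TruthTable:
    """Ground truth of a simulated experiment.

    ``genes``: per-gene class label, direction, trajectory label, and the set
    of responding bacteria (comma-joined). ``lfc``: planted log2FC per
    gene x condition x timepoint (rows only where nonzero structure was
    planted; null genes have no rows, i.e. planted log2FC 0 everywhere).
    """

    genes: pd.DataFrame
    lfc: pd.DataFrame

    def planted_lfc_lookup(self) -> dict[tuple[str, str, float], float]:
        return {
            (r.gene, r.condition, r.timepoint_h): r.lfc
            for r in self.lfc.itertuples(index=False)
        }

    def genes_of_class(self, klass: str) -> list[str]:
        sub = self.genes[self.genes["class"] == klass]
        return list(sub["gene"])

    def responding_bacteria(self, gene: str) -> set[str]:
        row = self.genes.loc[self.genes["gene"] == gene, "bacteria"]
        val = row.iloc[0]
        return set(val.split(",")) if isinstance(val, str) and val else set()


def _traj_scale(trajectory: str, timepoints: tuple[float, ...], tp: float) -> float:
    """Scale of the planted log2FC at timepoint tp for a trajectory class.

    Timepoints are mapped by rank (earliest/middle/latest) so the same scheme
    works for non-default timepoint grids.
    """
    order = sorted(set(timepoints))
    rank = order.index(tp)
    scales = TRAJECTORY_SCALES[trajectory]
    return scales[min(rank, len(scales) - 1)]


def simulate_experiment(
    config: SimConfig,
) -> tuple[CountMatrix, list[SampleRecord], TruthTable]:
    """Generate counts, a sample sheet, and the planted truth.

    Identical seeds give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(G)]

    live = [c for c in config.conditions if c.challenge_type == "live"]
    live_names = [c.name for c in live]
    sw_names = [c.name for c in config.conditions if c.challenge_type == "sterile_wound"]
    hk_names = [c.name for c in config.conditions if c.challenge_type == "heat_killed"]
    nonhigh_live = [c.name for c in live if len(c.timepoints) >= 3]
    cond_by_name = {c.name: c for c in config.conditions}

    # --- assign gene classes -------------------------------------------------
    perm = rng.permutation(G)
    class_of = np.array(["null"] * G, dtype=object)
    cursor = 0
    counts_per_class = {}
    for klass in GENE_CLASSES[:-1]:
        n = int(round(config.class_fractions.get(klass, 0.0) * G))
        counts_per_class[klass] = n
        class_of[perm[cursor : cursor + n]] = klass
        cursor += n

    traj_labels = list(config.trajectory_mix)
    traj_probs = np.array([config.trajectory_mix[t] for t in traj_labels])

    gene_rows = []
    lfc_rows: list[tuple[str, str, float, float]] = []

    uniq_cycle = 0
    for gi in range(G):
        klass = class_of[gi]
        gid = gene_ids[gi]
        direction = "none"
        trajectory = ""
        bacteria: list[str] = []

        def plant(conditions: list[str], sign: float, traj: str) -> None:
            for cname in conditions:
                spec = cond_by_name[cname]
                for tp in spec.timepoints:
                    scale = _traj_scale(traj, spec.timepoints, tp)
                    lfc = sign * config.lfc_magnitude * scale
                    if lfc != 0.0:
                        lfc_rows.append((gid, cname, tp, lfc))

        if klass in ("core_up", "core_down"):
            sign = 1.0 if klass == "core_up" else -1.0
            direction = "up" if sign > 0 else "down"
            trajectory = traj_labels[rng.choice(len(traj_labels), p=traj_probs)]
            bacteria = sorted(
                rng.choice(live_names, size=config.core_support, replace=False)
            )
            plant(bacteria, sign, trajectory)
        elif klass == "unique_per_bacterium":
            b = live_names[uniq_cycle % len(live_names)]
            uniq_cycle += 1
            sign = 1.0 if rng.random() < 0.5 else -1.0
            direction = "up" if sign > 0 else "down"
            trajectory = traj_labels[rng.choice(len(traj_labels), p=traj_probs)]
            bacteria = [b]
            plant(bacteria, sign, trajectory)
        elif klass == "wound_responsive":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            direction = "up" if sign > 0 else "down"
            trajectory = traj_labels[rng.choice(len(traj_labels), p=traj_probs)]
            plant(sw_names, sign, trajectory)
        elif klass == "hk_responsive":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            direction = "up" if sign > 0 else "down"
            trajectory = traj_labels[rng.choice(len(traj_labels), p=traj_probs)]
            plant(hk_names, sign, trajectory)
        elif klass == "signflip":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            direction = "up" if sign > 0 else "down"
            trajectory = "signflip"
            n_b = min(config.signflip_n_bacteria, len(nonhigh_live))
            bacteria = sorted(rng.choice(nonhigh_live, size=n_b, replace=False))
            for cname in bacteria:
                spec = cond_by_name[cname]
                order = sorted(set(spec.timepoints))
                # opposite-sign response at the first two timepoints, 0 after
                lfc_rows.append((gid, cname, order[0], sign * config.lfc_magnitude))
                if len(order) > 1:
                    lfc_rows.append(
                        (gid, cname, order[1], -sign * config.lfc_magnitude)
                    )

        gene_rows.append(
            {
                "gene": gid,
                "class": klass,
                "direction": direction,
                "trajectory": trajectory,
                "bacteria": ",".join(bacteria),
            }
        )

    lfc_df = pd.DataFrame(lfc_rows, columns=["gene", "condition", "timepoint_h", "lfc"])
    truth = TruthTable(genes=pd.DataFrame(gene_rows), lfc=lfc_df)

    # --- expected proportions and NB draws ----------------------------------
    baseline = rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sigma, G)
    base_prop = np.exp(baseline)
    base_prop /= base_prop.sum()
    mu_ref = config.lib_size_mean * base_prop  # baseline expected counts
    phi = config.dispersion_phi0 + config.dispersion_slope / np.maximum(mu_ref, 1.0)

    lfc_lookup: dict[tuple[str, float], np.ndarray] = {}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for r in lfc_df.itertuples(index=False):
        key = (r.condition, r.timepoint_h)
        if key not in lfc_lookup:
            lfc_lookup[key] = np.zeros(G)
        lfc_lookup[key][gene_pos[r.gene]] = r.lfc

    samples: list[SampleRecord] = []
    columns: list[np.ndarray] = []
    ln2 = math.log(2.0)
    sigma_lib = math.sqrt(math.log(1.0 + config.lib_size_cv**2))
    mu_lib = math.log(config.lib_size_mean) - 0.5 * sigma_lib**2
    for spec in config.conditions:
        for tp in spec.timepoints:
            for rep in range(1, spec.replicates + 1):
                sid = f"{spec.name}_{int(tp)}h_r{rep}"
                samples.append(
                    SampleRecord(
                        sample_id=sid,
                        condition=spec.name,
                        challenge_type=spec.challenge_type,
                        pgn_type=spec.pgn_type,
                        virulence=spec.virulence,
                        timepoint_h=tp,
                        replicate=rep,
                    )
                )
                lib = max(1.0, rng.lognormal(mu_lib, sigma_lib))
                lfc = lfc_lookup.get((spec.name, tp))
                rel = base_prop if lfc is None else base_prop * np.exp(lfc * ln2)
                p = rel / rel.sum()
                mu = lib * p
                n_param = 1.0 / phi
                y = rng.negative_binomial(n_param, n_param / (n_param + mu))
                columns.append(y.astype(np.int64))

    counts = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=[s.sample_id for s in samples],
        counts=np.column_stack(columns),
    )
    return counts, samples, truth


def simulate_two_group(
    n_genes: int,
    n_a: int,
    n_b: int,
    lib_size: float,
    phi: float,
    lfc_magnitude: float = 0.0,
    frac_de: float = 0.0,
    baseline_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, list[SampleRecord], np.ndarray]:
    """Minimal two-group NB experiment (one live condition vs unchallenged).

    A fraction ``frac_de`` of genes receives a planted log2FC of
    +/-``lfc_magnitude`` in group A. Returns the counts, sample sheet, and the
    planted per-gene log2FC vector (0 for null genes). Used for calibration
    and power checks where the full multi-condition design is unnecessary.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(0.0, baseline_sigma, n_genes)
    base_prop = np.exp(baseline)
    base_prop /= base_prop.sum()

    planted = np.zeros(n_genes)
    n_de = int(round(frac_de * n_genes))
    if n_de:
        idx = rng.choice(n_genes, size=n_de, replace=False)
        signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
        planted[idx] = signs * lfc_magnitude

    samples: list[SampleRecord] = []
    cols = []
    for group, n, cond in (("a", n_a, "Tr"), ("b", n_b, "UC")):
        for rep in range(1, n + 1):
            sid = f"{cond}_r{rep}"
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    condition=cond,
                    challenge_type="live" if group == "a" else "unchallenged",
                    pgn_type="DAP" if group == "a" else "none",
                    virulence="intermediate" if group == "a" else "none",
                    timepoint_h=12.0,
                    replicate=rep,
                )
            )
            rel = base_prop * np.exp(planted * math.log(2.0)) if group == "a" else base_prop
            p = rel / rel.sum()
            mu = lib_size * p
            if phi > 0:
                n_param = 1.0 / phi
                y = rng.negative_binomial(n_param, n_param / (n_param + mu))
            else:
                y = rng.poisson(mu)
            cols.append(y.astype(np.int64))

    counts = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=[s.sample_id for s in samples],
        counts=np.column_stack(cols),
    )
    return counts, samples, planted


IUPAC_CODES = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_promoters(
    gene_ids: list[str],
    motif: str = "TGCCACGT",
    planted_fraction: float = 0.2,
    length: int = 4000,
    gc: float = 0.43,
    seed: int = 0,
) -> tuple[list[SeqRecord], set[str]]:
    """Random promoter sequences with the motif planted in a known subset.

    Background bases are i.i.d. with the given GC content. Each planted
    promoter receives one exact (IUPAC-resolved) motif instance at a uniform
    random position on a uniform random strand. Returns Biopython records and
    the set of planted gene IDs.
    """
    motif = motif.upper()
    for i, ch in enumerate(motif):
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC symbol {ch!r} at motif position {i}")
    if length <= len(motif):
        raise ValueError("promoter length must exceed the motif length")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    bases = np.array(["A", "C", "G", "T"])
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    n_planted = int(round(planted_fraction * len(gene_ids)))
    planted = set(
        np.array(gene_ids, dtype=object)[
            rng.choice(len(gene_ids), size=n_planted, replace=False)
        ]
    )

    records = []
    for gid in gene_ids:
        seq = rng.choice(bases, size=length, p=probs)
        if gid in planted:
            instance = "".join(
                IUPAC_CODES[ch][rng.integers(len(IUPAC_CODES[ch]))] for ch in motif
            )
            if rng.random() < 0.5:
                instance = reverse_complement(instance)
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq[pos : pos + len(motif)] = list(instance)
        records.append(SeqRecord(Seq("".join(seq)), id=str(gid), description=""))
    return records, planted
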