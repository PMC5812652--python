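"""Tabular and sequence I/O plus the experiment's design structure.

All tabular files are tab-delimited UTF-8 with '.' as the decimal mark.
Result writers prepend a single ``#``-comment header line recording the
parameters and seed of the producing run, so every output is self-describing;
readers skip such lines. Gene and sample order as given in the counts file is
the canonical ordering used everywhere downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleRecord",
    "Design",
    "DataFormatError",
    "DesignError",
    "read_counts",
    "write_counts",
    "read_samplesheet",
    "write_samplesheet",
    "build_design",
    "read_gene_list",
    "write_gene_list",
    "read_table",
    "write_table",
]

CHALLENGE_TYPES = ("live", "heat_killed", "sterile_wound", "unchallenged")
PGN_TYPES = ("Lys", "DAP", "none")
VIRULENCE_LEVELS = ("low", "intermediate", "high", "none")


class DataFormatError(ValueError):
    """Malformed input file (bad cell, duplicate ID, unknown enum value)."""


class DesignError(ValueError):
    """Inconsistent experimental design (missing samples, too few replicates)."""


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    ``lib_size`` is always the per-sample column sum; it is recomputed on
    construction so the invariant cannot drift.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer dtype
    lib_size: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataFormatError("counts must be a 2-D gene x sample array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise DataFormatError(
                    f"non-integer count for gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise DataFormatError(
                f"negative count for gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise DataFormatError(f"duplicate {name} id {dup!r}")
        if len(self.gene_ids) == 0:
            raise DataFormatError("count matrix has no genes")
        self.lib_size = self.counts.sum(axis=0).astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep, :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one RNA-seq sample."""

    sample_id: str
    condition: str
    challenge_type: str
    pgn_type: str
    virulence: str
    timepoint_h: float
    replicate: int

    def __post_init__(self) -> None:
        if self.challenge_type not in CHALLENGE_TYPES:
            raise DataFormatError(
                f"sample {self.sample_id!r}: unknown challenge_type "
                f"{self.challenge_type!r}; allowed: {CHALLENGE_TYPES}"
            )
        if self.pgn_type not in PGN_TYPES:
            raise DataFormatError(
                f"sample {self.sample_id!r}: unknown pgn_type {self.pgn_type!r}; "
                f"allowed: {PGN_TYPES}"
            )
        if self.virulence not in VIRULENCE_LEVELS:
            raise DataFormatError(
                f"sample {self.sample_id!r}: unknown virulence {self.virulence!r}; "
                f"allowed: {VIRULENCE_LEVELS}"
            )
        # PGN chemistry only makes sense for bacterial challenges (live or dead).
        has_bacteria = self.challenge_type in ("live", "heat_killed")
        if has_bacteria and self.pgn_type == "none":
            raise DataFormatError(
                f"sample {self.sample_id!r}: bacterial challenge requires a "
                f"Lys or DAP pgn_type"
            )
        if not has_bacteria and self.pgn_type != "none":
            raise DataFormatError(
                f"sample {self.sample_id!r}: pgn_type must be 'none' for "
                f"{self.challenge_type} samples"
            )
        if self.replicate < 1:
            raise DataFormatError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


@dataclass
class Design:
    """Contrast structure: each (condition, timepoint) vs the pooled
    unchallenged control.

    The unchallenged samples from every timepoint are collapsed into one
    control pool; live infections, sterile wound, and heat-killed challenges
    are all contrasted against that same pool.
    """

    samples: list[SampleRecord]
    contrasts: list[tuple[str, float]]
    control_pool: list[str]

    def contrast_samples(self, condition: str, timepoint_h: float) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.condition == condition and s.timepoint_h == timepoint_h
        ]

    def replicate_groups(self) -> dict[tuple[str, float] | str, list[str]]:
        """All replicate groups: every contrast's treatment group plus the
        pooled control."""
        groups: dict = {"control_pool": list(self.control_pool)}
        for cond, tp in self.contrasts:
            groups[(cond, tp)] = self.contrast_samples(cond, tp)
        return groups

    def smallest_group_size(self) -> int:
        return min(len(g) for g in self.replicate_groups().values())

    def live_conditions(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.challenge_type == "live" and s.condition not in out:
                out.append(s.condition)
        return out

    def conditions_of_type(self, challenge_type: str) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.challenge_type == challenge_type and s.condition not in out:
                out.append(s.condition)
        return out

    def pgn_map(self) -> dict[str, str]:
        return {
            s.condition: s.pgn_type
            for s in self.samples
            if s.challenge_type == "live"
        }

    def three_timepoint_conditions(self) -> list[str]:
        """Conditions observed at all of 12/36/132 h (or whatever the full
        timepoint set is) -- those eligible for trajectory classification."""
        tps: dict[str, set[float]] = {}
        for s in self.samples:
            if s.challenge_type != "unchallenged":
                tps.setdefault(s.condition, set()).add(s.timepoint_h)
        full = max(tps.values(), key=len) if tps else set()
        return [c for c, t in tps.items() if t == full and len(t) >= 3]


def read_counts(path) -> CountMatrix:
    """Read a gene x sample TSV count matrix (first column gene IDs)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise DataFormatError(f"{path}: no data rows")
    genes = [str(g) for g in df.index]
    samples = [str(c) for c in df.columns]
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise DataFormatError(
                    f"{path}: non-integer count {raw!r} at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
            if val < 0:
                raise DataFormatError(
                    f"{path}: negative count at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                )
            counts[i, j] = val
    return CountMatrix(gene_ids=genes, sample_ids=samples, counts=counts)


def write_counts(cm: CountMatrix, path, params: dict | None = None) -> None:
    write_table(cm.to_frame(), path, params=params, index=True, index_label="gene")


def read_samplesheet(path) -> list[SampleRecord]:
    """Read the 7-column sample sheet; enum fields are case-normalized."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = [
        "sample_id",
        "condition",
        "challenge_type",
        "pgn_type",
        "virulence",
        "timepoint_h",
        "replicate",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                condition=str(row["condition"]),
                challenge_type=_norm_enum(row["challenge_type"]),
                pgn_type=_norm_pgn(row["pgn_type"]),
                virulence=_norm_enum(row["virulence"]),
                timepoint_h=float(row["timepoint_h"]),
                replicate=int(row["replicate"]),
            )
        )
    dup = _first_duplicate([r.sample_id for r in records])
    if dup is not None:
        raise DataFormatError(f"{path}: duplicate sample_id {dup!r}")
    return records


def _norm_enum(value) -> str:
    return str(value).strip().lower()


def _norm_pgn(value) -> str:
    v = str(value).strip().lower()
    return {"lys": "Lys", "dap": "DAP", "none": "none"}.get(v, str(value).strip())


def write_samplesheet(samples: list[SampleRecord], path, params: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "challenge_type": s.challenge_type,
                "pgn_type": s.pgn_type,
                "virulence": s.virulence,
                "timepoint_h": s.timepoint_h,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    )
    write_table(df, path, params=params)


def build_design(counts: CountMatrix, samples: list[SampleRecord]) -> Design:
    """One contrast per observed non-unchallenged (condition, timepoint) pair,
    each against the pooled unchallenged control."""
    sheet_ids = {s.sample_id for s in samples}
    count_ids = set(counts.sample_ids)
    for sid in counts.sample_ids:
        if sid not in sheet_ids:
            raise DesignError(f"sample {sid!r} in counts but missing from sample sheet")
    for sid in sorted(sheet_ids - count_ids):
        raise DesignError(f"sample {sid!r} in sample sheet but missing from counts")

    # canonical order: first appearance in the counts file
    order = {sid: i for i, sid in enumerate(counts.sample_ids)}
    samples = sorted(samples, key=lambda s: order[s.sample_id])

    control_pool = [s.sample_id for s in samples if s.challenge_type == "unchallenged"]
    if not control_pool:
        raise DesignError("no unchallenged samples: control pool is empty")

    contrasts: list[tuple[str, float]] = []
    for s in samples:
        if s.challenge_type == "unchallenged":
            continue
        key = (s.condition, s.timepoint_h)
        if key not in contrasts:
            contrasts.append(key)
    design = Design(samples=samples, contrasts=contrasts, control_pool=control_pool)
    for cond, tp in contrasts:
        n = len(design.contrast_samples(cond, tp))
        if n < 2:
            raise DesignError(
                f"contrast ({cond}, {tp} h) has {n} replicate(s); >= 2 required"
            )
    return design


def read_gene_list(path) -> set[str]:
    """One gene ID per line; '#' comments and blank lines skipped;
    duplicates collapsed."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


def write_gene_list(genes, path, params: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if params:
            fh.write(_param_header(params))
        for g in sorted(genes):
            fh.write(f"{g}\n")


def _param_header(params: dict) -> str:
    body = " ".join(f"{k}={params[k]}" for k in sorted(params))
    return f"# {body}\n"


def write_table(
    df: pd.DataFrame,
    path,
    params: dict | None = None,
    index: bool = False,
    index_label: str | None = None,
) -> None:
    """Write a TSV with an optional '# key=value ...' header comment line."""
    buf = io.StringIO()
    if params:
        buf.write(_param_header(params))
    df.to_csv(buf, sep="\t", index=index, index_label=index_label)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
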