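"""CPM, the low-count filter, and trimmed-mean-of-M-values (TMM) scaling.

TMM corrects for library composition: for each sample a precision-weighted
mean of per-gene log2 ratios (M-values) against a reference sample is taken
after trimming the most extreme 30% of genes by M and 5% by average abundance
(A), the method's standard trim fractions. Factors are rescaled so their
geometric mean is 1; the effective library size of sample k is N_k * f_k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import CountMatrix

__all__ = [
    "NormFactors",
    "cpm",
    "filter_low_counts",
    "choose_reference",
    "tmm_factors",
]

log = logging.getLogger(__name__)


@dataclass
class NormFactors:
    sample_ids: list[str]
    factors: np.ndarray  # f_k, geometric mean 1
    lib_size: np.ndarray
    reference: str
    effective_lib_size: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.lib_size = np.asarray(self.lib_size, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("all normalization factors must be > 0")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"geometric mean of factors is {gm}, expected 1")
        self.effective_lib_size = self.lib_size * self.factors

    def for_samples(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.effective_lib_size[[pos[s] for s in sample_ids]]


def unit_factors(counts: CountMatrix) -> NormFactors:
    """All-ones factors (no between-sample normalization)."""
    return NormFactors(
        sample_ids=list(counts.sample_ids),
        factors=np.ones(counts.n_samples),
        lib_size=counts.lib_size.astype(float),
        reference=counts.sample_ids[0],
    )


def cpm(counts: CountMatrix, factors: NormFactors | None = None) -> np.ndarray:
    """Counts per million: y_gk / (N_k * f_k) * 1e6 (f_k = 1 without factors)."""
    if np.any(counts.lib_size <= 0):
        bad = counts.sample_ids[int(np.argmax(counts.lib_size <= 0))]
        raise ValueError(f"sample {bad!r} has zero library size")
    eff = counts.lib_size.astype(float)
    if factors is not None:
        eff = factors.for_samples(counts.sample_ids)
    return counts.counts / eff[None, :] * 1e6


def filter_low_counts(
    counts: CountMatrix, cpm_threshold: float = 1.2, min_samples: int = 1
) -> CountMatrix:
    """Keep genes with CPM >= threshold in at least ``min_samples`` samples.

    CPM is unnormalized (f = 1) here, since filtering precedes TMM. The
    sensible default for ``min_samples`` is the smallest replicate-group size
    of the design (``Design.smallest_group_size()``), so that genes expressed
    in one full replicate group survive.
    """
    if cpm_threshold < 0:
        raise ValueError("cpm_threshold must be >= 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    c = cpm(counts)
    keep = (c >= cpm_threshold).sum(axis=1) >= min_samples
    kept = int(keep.sum())
    log.info(
        "low-count filter (CPM >= %g in >= %d samples): kept %d / %d genes",
        cpm_threshold,
        min_samples,
        kept,
        counts.n_genes,
    )
    return counts.subset_genes(keep)


def choose_reference(counts: CountMatrix) -> str:
    """Reference sample for TMM: the one whose 75th-percentile CPM is closest
    to the mean of per-sample 75th-percentile CPMs; ties break to the first
    sample in canonical order."""
    if counts.counts.sum() == 0:
        raise ValueError("cannot choose a TMM reference from an all-zero matrix")
    q75 = np.percentile(cpm(counts), 75, axis=0)
    dist = np.abs(q75 - q75.mean())
    return counts.sample_ids[int(np.argmin(dist))]


def _trim_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping ranks in [lo, n-lo) by ascending value, with
    lo = floor(n * trim); stable order so ties resolve deterministically."""
    n = len(values)
    lo = int(np.floor(n * trim))
    order = np.argsort(values, kind="stable")
    keep = np.zeros(n, dtype=bool)
    keep[order[lo : n - lo]] = True
    return keep


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> NormFactors:
    """TMM scaling factors against a reference sample.

    Per sample k vs reference r, over genes expressed in both (and excluding
    the degenerate case y = N):

        M_g = log2((y_gk/N_k) / (y_gr/N_r))
        A_g = 0.5 * log2((y_gk/N_k) * (y_gr/N_r))
        w_g = (N_k - y_gk)/(N_k y_gk) + (N_r - y_gr)/(N_r y_gr)

    genes in the top/bottom ``trim_m`` fraction by M and ``trim_a`` fraction
    by A are discarded; log2 f_k is the w-precision-weighted mean of the
    surviving M values. Factors are rescaled to geometric mean 1.
    """
    if reference is None:
        reference = choose_reference(counts)
    ridx = counts.sample_ids.index(reference)
    N = counts.lib_size.astype(float)
    yr = counts.counts[:, ridx].astype(float)

    log2f = np.zeros(counts.n_samples)
    for k in range(counts.n_samples):
        if k == ridx:
            continue
        yk = counts.counts[:, k].astype(float)
        ok = (yk > 0) & (yr > 0) & (yk < N[k]) & (yr < N[ridx])
        if ok.sum() == 0:
            warnings.warn(
                f"sample {counts.sample_ids[k]!r}: no usable genes vs reference; "
                f"factor set to 1"
            )
            continue
        pk = yk[ok] / N[k]
        pr = yr[ok] / N[ridx]
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        keep = _trim_keep(M, trim_m) & _trim_keep(A, trim_a)
        if keep.sum() < 10:
            warnings.warn(
                f"sample {counts.sample_ids[k]!r}: fewer than 10 genes survive "
                f"TMM trimming; factor set to 1"
            )
            continue
        w = (N[k] - yk[ok]) / (N[k] * yk[ok]) + (N[ridx] - yr[ok]) / (N[ridx] * yr[ok])
        log2f[k] = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])

    f = 2.0 ** (log2f - log2f.mean())  # geometric mean 1
    return NormFactors(
        sample_ids=list(counts.sample_ids),
        factors=f,
        lib_size=N,
        reference=reference,
    )
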