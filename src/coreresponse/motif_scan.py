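"""IUPAC consensus scanning of promoter sequences and set enrichment.

Matches a degenerate consensus (e.g. the CrebA-type element TGCCACGT) at
every offset of each promoter, on both strands by default. Overlapping
matches count individually; when a match and its reverse complement occupy
identical coordinates (palindromes) only the plus-strand hit is reported.
Enrichment of motif-bearing genes in a target set is assessed with the
upper-tail hypergeometric test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from scipy.stats import hypergeom

from .synthetic_data import IUPAC_CODES, reverse_complement

__all__ = ["MotifHits", "scan_consensus", "motif_enrichment"]

SEQ_ALPHABET = set("ACGTN")


@dataclass
class MotifHits:
    """Per-gene motif matches: {gene: [(offset, strand), ...]}."""

    motif: str
    both_strands: bool
    positions: dict[str, list[tuple[int, str]]]

    def hit_count(self, gene: str) -> int:
        return len(self.positions.get(gene, []))

    def genes_with_hits(self) -> set[str]:
        return {g for g, pos in self.positions.items() if pos}

    def total_hits(self) -> int:
        return sum(len(p) for p in self.positions.values())


def _motif_regex(motif: str) -> re.Pattern:
    """Overlap-aware regex for an IUPAC consensus (lookahead at each offset).

    Motif N matches any sequence base including N; every other symbol matches
    only its unambiguous base set, so sequence Ns never satisfy them.
    """
    parts = []
    for i, ch in enumerate(motif):
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC symbol {ch!r} at motif position {i}")
        allowed = IUPAC_CODES[ch] + ("N" if ch == "N" else "")
        parts.append(f"[{allowed}]" if len(allowed) > 1 else allowed)
    return re.compile(f"(?={''.join(parts)})")


def _scan_one(seq: str, pattern: re.Pattern) -> list[int]:
    return [m.start() for m in pattern.finditer(seq)]


def scan_consensus(seqs, motif: str, both_strands: bool = True) -> MotifHits:
    """Exact IUPAC-compatible matches of ``motif`` in each sequence record.

    ``seqs`` is an iterable of Biopython SeqRecords (or (id, sequence) pairs).
    Minus-strand hits are matches of the reverse-complemented motif, reported
    at their offset in the original sequence.
    """
    motif = motif.upper()
    plus_re = _motif_regex(motif)
    rc = reverse_complement(motif)
    minus_re = _motif_regex(rc) if both_strands else None
    bad_char = re.compile("[^ACGTN]")

    positions: dict[str, list[tuple[int, str]]] = {}
    for rec in seqs:
        if hasattr(rec, "seq"):
            gid, seq = str(rec.id), str(rec.seq).upper()
        else:
            gid, seq = str(rec[0]), str(rec[1]).upper()
        m = bad_char.search(seq)
        if m:
            raise ValueError(
                f"sequence {gid!r}: invalid character {m.group()!r} at "
                f"position {m.start()}"
            )
        plus = _scan_one(seq, plus_re)
        hits = [(i, "+") for i in plus]
        if minus_re is not None:
            plus_at = set(plus)
            # a minus hit at the same offset spans identical coordinates as a
            # plus hit (palindrome): report the plus-strand one only
            hits += [(i, "-") for i in _scan_one(seq, minus_re) if i not in plus_at]
        hits.sort()
        positions[gid] = hits
    return MotifHits(motif=motif, both_strands=both_strands, positions=positions)


def expected_background_hits(length: int, motif: str, gc: float) -> float:
    """Closed-form expected hit count (both strands) per i.i.d. background
    promoter: 2 * (L - m + 1) * prod(p(base)) for a non-degenerate motif."""
    p = 1.0
    for ch in motif.upper():
        base_p = 0.0
        for b in IUPAC_CODES[ch]:
            base_p += gc / 2 if b in "GC" else (1 - gc) / 2
        p *= base_p
    return 2.0 * (length - len(motif) + 1) * p


def motif_enrichment(
    hits: MotifHits, target_set: set[str], universe: set[str]
) -> tuple[int, float]:
    """Overlap of the target set with motif-bearing genes and its upper-tail
    hypergeometric p-value.

    Returns (k, p) with k = |target ∩ hit-genes|; p = P(X >= k) drawing
    |target| genes from a universe containing |hit-genes ∩ universe| marked
    genes.
    """
    if not target_set <= universe:
        raise ValueError("target set must be a subset of the universe")
    hit_genes = hits.genes_with_hits() & universe
    k = len(target_set & hit_genes)
    p = float(hypergeom.sf(k - 1, len(universe), len(hit_genes), len(target_set)))
    return k, min(p, 1.0)
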