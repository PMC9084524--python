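"""Binding-preference statistics from RNAcompete-style 7-mer Z-score tables.

An RNAcompete experiment summarises an RNA-binding protein's in vitro
affinity as a one-sided Z-score per RNA 7-mer (higher = stronger preferred
binding).  The statistics here characterise what the top-scoring 7-mers
look like: how much of the cumulative top-score mass is carried by 7-mers
containing a literal motif (e.g. GCUU or GCAGC), how the base following a
GC dinucleotide partitions that mass, and the relative weight of GC pairs
spaced by one versus two bases (GCxGC vs GCxxGC).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

RNA_BASES = "ACGU"
KMER_LEN = 7

__all__ = [
    "KmerZscoreTable",
    "MotifSet",
    "UndefinedStatisticError",
    "read_kmer_table",
    "top_kmers",
    "max_zscore",
    "motif_contribution",
    "gc_following_base_partition",
    "gc_spacing_log_ratio",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined on this input (e.g. non-positive Z mass)."""


def _normalize_kmer(kmer: str) -> str:
    return kmer.strip().upper().replace("T", "U")


@dataclass
class KmerZscoreTable:
    """Map from RNA 7-mer to its one-sided Z-score.

    The Z-score is a unitless affinity proxy.  K-mers are normalised to
    the RNA alphabet (T -> U) and must be unique and exactly 7 nt long.
    """

    z: pd.Series  # index: 7-mer strings, values: float Z-scores

    def __post_init__(self) -> None:
        idx = pd.Index([_normalize_kmer(k) for k in self.z.index])
        z = pd.Series(self.z.to_numpy(dtype=float), index=idx)
        bad = [k for k in z.index if len(k) != KMER_LEN or set(k) - set(RNA_BASES)]
        if bad:
            raise ValueError(f"invalid 7-mers in table: {bad[:5]}")
        if z.index.has_duplicates:
            dups = z.index[z.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate 7-mers in table: {dups[:5]}")
        n_missing = int(z.isna().sum())
        if n_missing:
            logger.info("dropping %d 7-mers with missing Z-scores", n_missing)
            z = z.dropna()
        self.z = z

    def __len__(self) -> int:
        return len(self.z)

    @classmethod
    def from_dict(cls, entries: dict) -> "KmerZscoreTable":
        return cls(pd.Series(entries, dtype=float))


@dataclass
class MotifSet:
    """Non-empty set of literal RNA motifs, each at most 7 nt."""

    motifs: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        motifs = tuple(_normalize_kmer(m) for m in self.motifs)
        if not motifs:
            raise ValueError("motif set must be non-empty")
        for m in motifs:
            if not m or len(m) > KMER_LEN or set(m) - set(RNA_BASES):
                raise ValueError(f"invalid motif {m!r}: must be 1-7 nt over ACGU")
        self.motifs = motifs

    def matches(self, kmer: str) -> bool:
        return any(m in kmer for m in self.motifs)


def _as_table(table) -> KmerZscoreTable:
    if isinstance(table, KmerZscoreTable):
        return table
    if isinstance(table, pd.Series):
        return KmerZscoreTable(table)
    return KmerZscoreTable.from_dict(dict(table))


def _as_motifs(motifs) -> MotifSet:
    if isinstance(motifs, MotifSet):
        return motifs
    if isinstance(motifs, str):
        return MotifSet((motifs,))
    return MotifSet(tuple(motifs))


def read_kmer_table(path) -> KmerZscoreTable:
    """Read a two-column tab-separated (kmer, zscore) table.

    An optional single header line is detected by a non-numeric second
    field.  DNA-alphabet tables are converted to RNA at load.
    """
    entries = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                z = float(fields[1])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric Z-score {fields[1]!r}")
            kmer = _normalize_kmer(fields[0])
            if kmer in entries:
                raise ValueError(f"{path}:{lineno}: duplicate 7-mer {kmer}")
            entries[kmer] = z
    return KmerZscoreTable.from_dict(entries)


def top_kmers(table, n: int):
    """Return the ``min(n, len(table))`` highest-Z 7-mers, descending.

    Ties on Z are broken lexicographically (smaller k-mer first) so the
    top-n boundary is deterministic and order-independent.
    """
    tab = _as_table(table)
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(tab) == 0:
        raise ValueError("empty table")
    ordered = sorted(tab.z.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[: min(n, len(ordered))]


def max_zscore(table) -> float:
    """Z-score of the single top 7-mer."""
    tab = _as_table(table)
    if len(tab) == 0:
        raise ValueError("empty table")
    return float(tab.z.max())


def motif_contribution(table, motifs, n: int = 100) -> float:
    """Fraction of the cumulative top-n Z-score carried by motif-containing 7-mers.

    The Z-scores of all top-n 7-mers containing at least one motif of the
    set as a literal substring are summed and divided by the Z-sum of all
    top-n 7-mers.  Multiply by 100 for the percent scale.
    """
    mset = _as_motifs(motifs)
    top = top_kmers(table, n)
    total = sum(z for _, z in top)
    if total <= 0:
        raise UndefinedStatisticError("total top-n Z-score sum is not positive")
    hit = sum(z for k, z in top if mset.matches(k))
    return hit / total


def _single_gc_position(kmer: str):
    """Start index of the unique GC occurrence, or None if not exactly one.

    Overlap cannot occur for the 2-mer GC, so a simple scan suffices.
    """
    positions = [i for i in range(len(kmer) - 1) if kmer[i : i + 2] == "GC"]
    if len(positions) != 1:
        return None
    return positions[0]


def gc_following_base_partition(table, n: int = 100, single_gc: bool = True) -> dict:
    """Partition top-n Z mass by the base following a GC dinucleotide.

    With ``single_gc=True`` (default) only 7-mers with exactly one GC
    occurrence are considered, making the following-base class
    unambiguous; a GC occupying the final two positions has no following
    base and such 7-mers are excluded.  With ``single_gc=False`` every
    GCA/GCC/GCG/GCU occurrence credits its class with the 7-mer's Z.
    Returns fractions over {A, C, G, U} normalised to sum to 1.
    """
    top = top_kmers(table, n)
    sums = {b: 0.0 for b in RNA_BASES}
    for kmer, z in top:
        if single_gc:
            pos = _single_gc_position(kmer)
            if pos is None or pos + 2 >= len(kmer):
                continue
            sums[kmer[pos + 2]] += z
        else:
            for b in RNA_BASES:
                if "GC" + b in kmer:
                    sums[b] += z
    total = sum(sums.values())
    if total <= 0:
        raise UndefinedStatisticError("no qualifying GC-containing 7-mers in top-n")
    return {b: s / total for b, s in sums.items()}


_GC_X_GC = re.compile("GC.GC")
_GC_XX_GC = re.compile("GC..GC")


def gc_spacing_log_ratio(table, n: int = 100) -> float:
    """log2 ratio of top-n Z mass for GCxGC- versus GCxxGC-containing 7-mers.

    Raises :class:`UndefinedStatisticError` when either spacing class is
    absent from the top-n or has a non-positive Z-sum; callers should
    report the statistic as missing in that case.  A 7-mer matching both
    patterns (impossible within 7 nt, handled defensively) counts in both.
    """
    top = top_kmers(table, n)
    sum_1 = sum(z for k, z in top if _GC_X_GC.search(k))
    sum_2 = sum(z for k, z in top if _GC_XX_GC.search(k))
    if sum_1 <= 0 or sum_2 <= 0:
        raise UndefinedStatisticError(
            "GCxGC/GCxxGC log-ratio undefined: "
            f"class sums {sum_1:.3g} (GCxGC) and {sum_2:.3g} (GCxxGC)"
        )
    return math.log2(sum_1 / sum_2)
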