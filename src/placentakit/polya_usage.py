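"""PolyA-site calling and differential proximal/distal usage from 3'-seq.

Reverse-primed 3'-end libraries (QuantSeq REV style) place the 5' end of
each alignment at the transcript cleavage position, on the strand
opposite to the mRNA.  The pipeline here:

1. infers cleavage sites per read (strand inversion, 5'-end coordinate),
2. clusters reads into polyA sites by greedy peak picking with a +/-50 nt
   tolerance,
3. removes likely internal-priming artifacts (no upstream polyA-signal
   hexamer AND an A-rich downstream genomic context),
4. quantifies percent usage (PU) of the proximal site of a per-gene
   proximal/distal pair,
5. tests per-pair condition-dependent usage with a 2x2 contingency test
   and Benjamini-Hochberg FDR across pairs, and
6. selects one representative pair per gene by a ranked read-support rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ThreePrimeRead",
    "PolyASite",
    "PolyAPair",
    "PairTestResult",
    "read_three_prime_bed",
    "read_three_prime_tsv",
    "read_genome_fasta",
    "infer_cleavage_site",
    "call_sites",
    "filter_internal_priming",
    "make_pair",
    "proximal_usage",
    "test_pair",
    "test_pairs",
    "select_representative_pair",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ThreePrimeRead:
    """A 3'-seq alignment reduced to its informative coordinates."""

    chrom: str
    alignment_strand: str  # '+' or '-'
    five_prime_pos: int  # 1-based position of the alignment's 5' end
    sample_id: str

    def __post_init__(self) -> None:
        if self.alignment_strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.alignment_strand!r}")
        if self.five_prime_pos < 1:
            raise ValueError("positions are 1-based; must be >= 1")


@dataclass
class PolyASite:
    """A called cleavage/polyadenylation site."""

    chrom: str
    mrna_strand: str  # inverse of the alignment strand
    position: int  # 1-based cleavage coordinate (the cluster peak)
    support: int  # total reads assigned to the site
    sample_counts: Dict[str, int] = field(default_factory=dict)
    signal_ok: Optional[bool] = None  # set by filter_internal_priming

    @property
    def key(self) -> Tuple[str, str, int]:
        return (self.chrom, self.mrna_strand, self.position)


@dataclass
class PolyAPair:
    """Per-gene proximal/distal polyA-site pair with per-sample counts.

    Proximal is 5' of distal in mRNA orientation: the smaller coordinate
    on '+' mRNA strand, the larger on '-'.
    """

    gene_id: str
    proximal: PolyASite
    distal: PolyASite
    pair_id: str = ""

    def __post_init__(self) -> None:
        if (self.proximal.chrom, self.proximal.mrna_strand) != (
            self.distal.chrom,
            self.distal.mrna_strand,
        ):
            raise ValueError("pair sites must share chromosome and mRNA strand")
        strand = self.proximal.mrna_strand
        if strand == "+" and not self.proximal.position < self.distal.position:
            raise ValueError("proximal must be 5' of distal (smaller coord on '+')")
        if strand == "-" and not self.proximal.position > self.distal.position:
            raise ValueError("proximal must be 5' of distal (larger coord on '-')")
        if not self.pair_id:
            self.pair_id = (
                f"{self.gene_id}:{self.proximal.position}-{self.distal.position}"
            )

    def counts(self, samples: Sequence[str]) -> np.ndarray:
        """2 x len(samples) matrix of (proximal, distal) read counts."""
        return np.array(
            [
                [self.proximal.sample_counts.get(s, 0) for s in samples],
                [self.distal.sample_counts.get(s, 0) for s in samples],
            ]
        )

    @property
    def total_reads(self) -> int:
        return sum(self.proximal.sample_counts.values()) + sum(
            self.distal.sample_counts.values()
        )


@dataclass
class PairTestResult:
    """Differential-usage call for one pair in one KO-vs-WT comparison."""

    pair_id: str
    gene_id: str
    comparison: str
    log2fc: float  # log2 fold change of proximal usage, KO over WT
    pvalue: float
    fdr: float
    status: str  # enhanced | repressed | ko_up | ko_down | ns
    continuity_corrected: bool = False


def read_three_prime_bed(path) -> List[ThreePrimeRead]:
    """Read 3'-seq alignments from BED6 (0-based half-open, name=sample_id)."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            five_prime = start + 1 if strand == "+" else end
            reads.append(ThreePrimeRead(chrom, strand, five_prime, name))
    return reads


def read_three_prime_tsv(path) -> List[ThreePrimeRead]:
    """Read a ``chrom strand five_prime_pos sample_id`` TSV (1-based)."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            chrom, strand, pos, sample = fields
            reads.append(ThreePrimeRead(chrom, strand, int(pos), sample))
    return reads


def read_genome_fasta(path) -> Dict[str, str]:
    """Load a genome FASTA into a chrom -> uppercase sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def infer_cleavage_site(read: ThreePrimeRead) -> Tuple[str, str, int]:
    """(chrom, mRNA strand, cleavage position) for one reverse-primed read.

    The mRNA strand is the inverse of the alignment strand and the
    cleavage position is the alignment's 5'-end coordinate.
    """
    mrna_strand = "-" if read.alignment_strand == "+" else "+"
    return (read.chrom, mrna_strand, read.five_prime_pos)


def call_sites(
    reads: Sequence[ThreePrimeRead], tolerance: int = 50, min_support: int = 1
) -> List[PolyASite]:
    """Greedy peak clustering of inferred cleavage positions into polyA sites.

    Per chromosome and mRNA strand: repeatedly take the position with the
    highest read count, absorb all unassigned reads within +/-tolerance
    into a site at that peak position, and stop once the best remaining
    cluster's support falls below ``min_support``.  Every read is
    assigned to at most one site, so assignments partition the reads.
    Ties on peak support are broken toward the smaller coordinate.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_locus: Dict[Tuple[str, str], Dict[int, Dict[str, int]]] = {}
    for read in reads:
        chrom, strand, pos = infer_cleavage_site(read)
        per_pos = by_locus.setdefault((chrom, strand), {})
        per_sample = per_pos.setdefault(pos, {})
        per_sample[read.sample_id] = per_sample.get(read.sample_id, 0) + 1

    sites: List[PolyASite] = []
    for (chrom, strand), per_pos in sorted(by_locus.items()):
        pos_counts = {p: sum(sc.values()) for p, sc in per_pos.items()}
        while pos_counts:
            # deterministic peak: max count, then smallest coordinate
            peak = min(pos_counts, key=lambda p: (-pos_counts[p], p))
            members = [p for p in pos_counts if abs(p - peak) <= tolerance]
            support = sum(pos_counts[p] for p in members)
            if support < min_support:
                break
            sample_counts: Dict[str, int] = {}
            for p in members:
                for sample, c in per_pos[p].items():
                    sample_counts[sample] = sample_counts.get(sample, 0) + c
                del pos_counts[p]
            sites.append(PolyASite(chrom, strand, peak, support, sample_counts))
    return sites


def _upstream_downstream(site: PolyASite, genome: Dict[str, str],
                         up_window: Tuple[int, int], down_len: int):
    """mRNA-sense upstream-window and downstream sequences around a site."""
    seq = genome.get(site.chrom)
    if seq is None:
        raise ValueError(f"chromosome {site.chrom!r} missing from genome")
    lo_off, hi_off = up_window  # nt upstream, e.g. (10, 40)
    pos = site.position  # 1-based
    if site.mrna_strand == "+":
        up = seq[max(0, pos - hi_off - 1) : max(0, pos - lo_off)]
        down = seq[pos : pos + down_len]
    else:
        up = _revcomp(seq[pos + lo_off - 1 : pos + hi_off])
        down = _revcomp(seq[max(0, pos - down_len - 1) : pos - 1])
    if pos > len(seq):
        raise ValueError(f"site {site.key} outside chromosome bounds")
    return up, down


def filter_internal_priming(
    sites: Sequence[PolyASite],
    genome: Dict[str, str],
    signal_hexamers: Sequence[str] = ("AATAAA", "ATTAAA"),
    signal_window: Tuple[int, int] = (10, 40),
    a_run: int = 6,
    a_window: Tuple[int, int] = (20, 12),
    return_removed: bool = False,
):
    """Remove likely internal-priming sites (oligo-dT priming on genomic A-tracts).

    A site is kept iff a polyA-signal hexamer occurs in the mRNA-sense
    window ``signal_window`` nt upstream of the cleavage position, OR the
    downstream genomic context is not A-rich (no run of >= ``a_run`` A's
    and fewer than ``a_window[1]`` A's within the ``a_window[0]`` nt
    downstream).  Removed sites are logged with the reason; kept sites
    get ``signal_ok`` set.
    """
    down_len, max_a = a_window
    kept, removed = [], []
    for site in sites:
        up, down = _upstream_downstream(site, genome, signal_window, down_len)
        has_signal = any(h in up for h in signal_hexamers)
        a_rich = ("A" * a_run in down) or (down.count("A") >= max_a)
        site.signal_ok = has_signal
        if has_signal or not a_rich:
            kept.append(site)
        else:
            reason = "A-rich downstream, no upstream polyA signal"
            logger.info("removed site %s: %s", site.key, reason)
            removed.append((site, reason))
    if return_removed:
        return kept, removed
    return kept


def make_pair(gene_id: str, site_a: PolyASite, site_b: PolyASite) -> PolyAPair:
    """Order two sites of one gene into a proximal/distal pair."""
    strand = site_a.mrna_strand
    first, second = sorted([site_a, site_b], key=lambda s: s.position)
    prox, dist = (first, second) if strand == "+" else (second, first)
    return PolyAPair(gene_id, prox, dist)


def proximal_usage(pair: PolyAPair, sample: str) -> Optional[float]:
    """Percent usage (PU) of the proximal site in one sample.

    100 * proximal / (proximal + distal); None when the pair has no reads
    in the sample (missing value, not 0).
    """
    p = pair.proximal.sample_counts.get(sample, 0)
    d = pair.distal.sample_counts.get(sample, 0)
    if p + d == 0:
        return None
    return 100.0 * p / (p + d)


def _pair_comparison_stats(pair: PolyAPair, ko_samples, wt_samples):
    """(log2FC of proximal usage KO/WT, p-value, continuity flag) for one pair."""
    ko = pair.counts(ko_samples).sum(axis=1)  # [prox, dist], replicates summed
    wt = pair.counts(wt_samples).sum(axis=1)
    table = np.array([ko, wt], dtype=float)  # rows: condition, cols: prox/dist
    corrected = False
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        table = table + 0.5  # Haldane continuity correction for a zero margin
        corrected = True
    usage_ko = table[0, 0] / table[0].sum()
    usage_wt = table[1, 0] / table[1].sum()
    log2fc = math.log2(usage_ko / usage_wt) if usage_ko > 0 and usage_wt > 0 else (
        math.inf if usage_ko > 0 else (-math.inf if usage_wt > 0 else 0.0)
    )
    # p-value from the raw table; a zero margin yields p = 1 under Fisher,
    # only the usage estimate needs the continuity correction
    _, p = stats.fisher_exact(np.array([ko, wt], dtype=int))
    return float(log2fc), float(p), corrected


def test_pairs(
    pairs: Sequence[PolyAPair],
    design: Dict[str, str],
    comparisons: Sequence[Tuple[str, str]],
    fdr_threshold: float = 0.1,
) -> List[PairTestResult]:
    """Test condition-dependent proximal/distal usage for a set of pairs.

    ``design`` maps sample -> condition; ``comparisons`` lists
    (ko_condition, wt_condition) contrasts.  Replicates are summed into a
    2x2 (site x condition) table tested with Fisher's exact test;
    Benjamini-Hochberg correction is applied across all pairs within
    each comparison.  A pair is 'enhanced' when the proximal site is
    up-regulated in the KO at FDR < threshold (the two sites' usage
    fractions then necessarily move in opposite directions), 'repressed'
    when down-regulated; non-significant directional calls are
    'ko_up'/'ko_down' and flat pairs are 'ns'.
    """
    by_cond: Dict[str, List[str]] = {}
    for sample, cond in design.items():
        by_cond.setdefault(cond, []).append(sample)
    results: List[PairTestResult] = []
    for ko_cond, wt_cond in comparisons:
        ko_samples = sorted(by_cond.get(ko_cond, []))
        wt_samples = sorted(by_cond.get(wt_cond, []))
        if not ko_samples or not wt_samples:
            raise ValueError(f"comparison {ko_cond} vs {wt_cond}: empty condition")
        rows = []
        for pair in pairs:
            if pair.total_reads == 0:
                raise ValueError(f"pair {pair.pair_id} has no reads")
            log2fc, p, corrected = _pair_comparison_stats(pair, ko_samples, wt_samples)
            rows.append((pair, log2fc, p, corrected))
        fdrs = multipletests([r[2] for r in rows], method="fdr_bh")[1]
        comparison = f"{ko_cond}_vs_{wt_cond}"
        for (pair, log2fc, p, corrected), fdr in zip(rows, fdrs):
            if log2fc > 0:
                status = "enhanced" if fdr < fdr_threshold else "ko_up"
            elif log2fc < 0:
                status = "repressed" if fdr < fdr_threshold else "ko_down"
            else:
                status = "ns"
            results.append(
                PairTestResult(
                    pair.pair_id, pair.gene_id, comparison, log2fc, p, float(fdr),
                    status, corrected,
                )
            )
    return results


def test_pair(
    pair: PolyAPair,
    design: Dict[str, str],
    comparisons: Sequence[Tuple[str, str]],
    fdr_threshold: float = 0.1,
) -> List[PairTestResult]:
    """Single-pair convenience wrapper (FDR equals the raw p-value)."""
    return test_pairs([pair], design, comparisons, fdr_threshold)


def select_representative_pair(
    gene_pairs: Sequence[PolyAPair],
    results: Sequence[PairTestResult],
    read_frac_1: float = 0.15,
    read_frac_2: float = 0.30,
    max_read_fallback: bool = True,
):
    """Pick one representative polyA pair for a gene by ranked read support.

    Candidates are the gene's pairs significant (enhanced/repressed) in
    the maximal number of KO-vs-WT comparisons.  Then, ranked:

    (i)   the candidate with the largest |log2FC| is taken if its total
          reads are at least ``read_frac_1`` of the gene's max-read pair;
    (ii)  else the max-read pair among ALL pairs is taken (disable with
          ``max_read_fallback=False``);
    (iii) else, if the largest-|FC| candidate exceeds ``read_frac_2`` of
          the max reads, it is taken;
    (iv)  else the gene is discarded (returns None).

    Returns (selected pair or None, decision trace as a list of strings).
    """
    if not gene_pairs:
        raise ValueError("at least one pair required")
    trace: List[str] = []
    by_pair: Dict[str, List[PairTestResult]] = {}
    for res in results:
        by_pair.setdefault(res.pair_id, []).append(res)
    n_sig = {
        p.pair_id: sum(
            r.status in ("enhanced", "repressed") for r in by_pair.get(p.pair_id, [])
        )
        for p in gene_pairs
    }
    max_sig = max(n_sig.values())
    candidates = [p for p in gene_pairs if n_sig[p.pair_id] == max_sig]
    trace.append(f"candidates significant in {max_sig} comparison(s): "
                 f"{[p.pair_id for p in candidates]}")

    def max_abs_fc(pair: PolyAPair) -> float:
        fcs = [abs(r.log2fc) for r in by_pair.get(pair.pair_id, [])
               if math.isfinite(r.log2fc)]
        return max(fcs, default=0.0)

    max_read_pair = max(gene_pairs, key=lambda p: (p.total_reads, p.pair_id))
    max_reads = max_read_pair.total_reads
    best_fc = max(candidates, key=lambda p: (max_abs_fc(p), p.pair_id))

    if max_reads > 0 and best_fc.total_reads >= read_frac_1 * max_reads:
        trace.append(
            f"(i) largest-|FC| candidate {best_fc.pair_id} has "
            f"{best_fc.total_reads} >= {read_frac_1:.0%} of {max_reads} reads: selected"
        )
        return best_fc, trace
    trace.append(
        f"(i) largest-|FC| candidate {best_fc.pair_id} below "
        f"{read_frac_1:.0%} of max reads ({best_fc.total_reads}/{max_reads})"
    )
    if max_read_fallback:
        trace.append(f"(ii) max-read pair {max_read_pair.pair_id} selected")
        return max_read_pair, trace
    trace.append("(ii) max-read fallback disabled")
    if max_reads > 0 and best_fc.total_reads > read_frac_2 * max_reads:
        trace.append(
            f"(iii) candidate {best_fc.pair_id} exceeds {read_frac_2:.0%} "
            f"of max reads: selected"
        )
        return best_fc, trace
    trace.append("(iv) gene discarded")
    return None, trace
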