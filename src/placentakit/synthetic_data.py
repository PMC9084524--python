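"""Synthetic inputs with planted structure for every pipeline stage.

Each generator emulates one of the pipeline's input types with known
ground truth, so parameter recovery can be tested end to end without
external data: 7-mer affinity tables with planted motif bonuses, multinomial
junction counts over donor classes, litter-structured weights with a
genotype effect, two-site 3'-seq genes with condition-dependent proximal
usage and A-rich internal-priming decoys, PSI tables with planted
delta-PSI events, and TPM matrices with planted tissue-enriched genes.

All randomness flows through one `numpy` Generator seeded per call, so a
fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .motif_metrics import KMER_LEN, RNA_BASES, KmerZscoreTable, _normalize_kmer
from .polya_usage import PolyASite, ThreePrimeRead
from .tss_usage import JunctionCountTable

__all__ = [
    "SimConfig",
    "GeneModel",
    "gen_kmer_zscore_table",
    "gen_junction_counts",
    "gen_litter_weights",
    "gen_three_prime_reads",
    "gen_psi_table",
    "gen_expression_matrix",
    "write_kmer_table",
    "write_junction_table",
    "write_weights_table",
    "write_reads_bed",
    "write_genome_fasta",
    "write_expression_matrix",
]


@dataclass
class SimConfig:
    """Bundle of per-generator parameter blocks plus one master seed.

    Any block left empty falls back to the generator defaults, which are
    the package's reference study conditions (documented in the methods
    note).  Fractions must lie in [0, 1] and sizes must be positive.
    """

    seed: int = 0
    kmer: dict = field(default_factory=dict)
    junctions: dict = field(default_factory=dict)
    litters: dict = field(default_factory=dict)
    three_prime: dict = field(default_factory=dict)
    psi: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# 7-mer Z-score tables

def gen_kmer_zscore_table(
    planted_motifs: Dict[str, float],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> KmerZscoreTable:
    """Full 4^7 = 16,384-row 7-mer table with planted motif bonuses.

    Z(kmer) = sum of bonuses of planted motifs contained in the k-mer as
    literal substrings, plus Gaussian(0, noise_sd) noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    motifs = {}
    for motif, bonus in planted_motifs.items():
        m = _normalize_kmer(motif)
        if not m or len(m) > KMER_LEN or set(m) - set(RNA_BASES):
            raise ValueError(f"invalid planted motif {motif!r}")
        motifs[m] = float(bonus)
    kmers = ["".join(p) for p in itertools.product(RNA_BASES, repeat=KMER_LEN)]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(kmers)) if noise_sd > 0 else np.zeros(len(kmers))
    z = np.array(
        [sum(b for m, b in motifs.items() if m in k) for k in kmers], dtype=float
    )
    return KmerZscoreTable(pd.Series(z + noise, index=kmers))


def write_kmer_table(table: KmerZscoreTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tzscore\n")
        for kmer, z in table.z.items():
            fh.write(f"{kmer}\t{z:.6g}\n")


# ---------------------------------------------------------------------------
# Junction counts over donor classes

def gen_junction_counts(
    profiles: Dict[str, Dict[str, float]],
    depth: int = 10_000,
    n_samples_per_group: int = 2,
    seed: int = 0,
    acceptor_id: str = "acceptor_11",
):
    """Multinomial junction counts over donor classes, per sample group.

    ``profiles`` maps group -> {donor class: expected read fraction};
    fractions per group must sum to 1.  One donor is emitted per donor
    class, all splicing to the shared reference acceptor.  Returns
    (JunctionCountTable, donor annotation DataFrame, sample->group Series).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    classes = sorted({cls for prof in profiles.values() for cls in prof})
    annotation = pd.DataFrame(
        {
            "chrom": "chrX",
            "pos": [132_400_000 + 1_000 * i for i in range(len(classes))],
            "class": classes,
        },
        index=pd.Index([f"donor_{i}" for i in range(len(classes))], name="donor_id"),
    )
    donor_of_class = {cls: f"donor_{i}" for i, cls in enumerate(classes)}
    rows = []
    grouping = {}
    for group in sorted(profiles):
        prof = profiles[group]
        fracs = np.array([prof.get(cls, 0.0) for cls in classes], dtype=float)
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions for group {group!r} must sum to 1")
        for rep in range(1, n_samples_per_group + 1):
            sample = f"{group}_{rep}"
            grouping[sample] = group
            counts = rng.multinomial(depth, fracs)
            for cls, c in zip(classes, counts):
                rows.append((sample, donor_of_class[cls], acceptor_id, int(c)))
    table = JunctionCountTable(
        pd.DataFrame(rows, columns=["sample_id", "donor_id", "acceptor_id", "count"])
    )
    return table, annotation, pd.Series(grouping, name="group")


def write_junction_table(table: JunctionCountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# sample_id\tdonor_id\tacceptor_id\tcount\n")
        for row in table.records.itertuples(index=False):
            fh.write(f"{row.sample_id}\t{row.donor_id}\t{row.acceptor_id}\t{row.count}\n")


# ---------------------------------------------------------------------------
# Litter-structured weights

def gen_litter_weights(
    n_litters: int = 6,
    litter_size_range: Tuple[int, int] = (6, 10),
    baseline_mean: float = 0.10,
    baseline_sd: float = 0.012,
    effect: float = 0.012,
    noise_sd: float = 0.008,
    seed: int = 0,
    tissue: str = "placenta",
    truncate: bool = True,
    truncate_at: float = 1e-3,
) -> pd.DataFrame:
    """Litter-structured weights with an additive genotype effect.

    weight = litter baseline + effect * 1[KO] + Gaussian(0, noise_sd),
    with the litter baseline drawn once per litter from
    Gaussian(baseline_mean, baseline_sd).  Defaults emulate E18.5 mouse
    placenta weights in grams with a KO effect of roughly +12%.  Each
    litter receives floor(size/2) KO and the rest WT animals, so both
    genotypes are always present.  Non-positive weights are truncated at
    ``truncate_at`` grams (keeping litter sizes intact) or raise when
    ``truncate=False``.
    """
    if n_litters < 1:
        raise ValueError("n_litters must be >= 1")
    lo, hi = litter_size_range
    if lo < 2:
        raise ValueError("litters need at least 2 animals for both genotypes")
    rng = np.random.default_rng(seed)
    rows = []
    for li in range(1, n_litters + 1):
        size = int(rng.integers(lo, hi + 1))
        baseline = rng.normal(baseline_mean, baseline_sd)
        n_ko = size // 2
        genos = np.array(["KO"] * n_ko + ["WT"] * (size - n_ko))
        rng.shuffle(genos)
        for si, geno in enumerate(genos, start=1):
            w = baseline + (effect if geno == "KO" else 0.0) + rng.normal(0, noise_sd)
            if w <= 0:
                if not truncate:
                    raise ValueError(
                        "simulated non-positive weight; enable truncation or "
                        "adjust parameters"
                    )
                w = truncate_at
            mat, pat = ("-", "-") if geno == "KO" else ("+", "+")
            rows.append(
                (f"litter{li}", f"litter{li}_pup{si}", tissue, float(w),
                 "Mbnl3", mat, pat, "F", geno)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "litter_id", "specimen_id", "tissue", "weight", "gene",
            "maternal_allele", "paternal_allele", "sex", "effective_genotype",
        ],
    )


def write_weights_table(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"weight": "weight_g"})
    cols = [
        "litter_id", "specimen_id", "tissue", "weight_g", "gene",
        "maternal_allele", "paternal_allele", "sex", "effective_genotype",
    ]
    out[[c for c in cols if c in out.columns]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# 3'-seq reads with internal-priming decoys

@dataclass
class GeneModel:
    """A two-polyA-site gene on its own synthetic chromosome ('+' mRNA strand)."""

    gene_id: str
    proximal_pos: int = 1_000
    distal_pos: int = 1_400
    decoy_pos: int = 2_000  # A-rich internal-priming decoy, no upstream signal

    @property
    def chrom(self) -> str:
        return f"chr_{self.gene_id}"


_NON_A_PATTERN = "CTGCGTCGTGCCTGCGTCGTGCCTG"


def _build_chromosome(model: GeneModel, rng: np.random.Generator,
                      signal_offset: int = 30) -> str:
    """Synthetic chromosome: random background, planted signals, scrubbed decoy."""
    length = max(model.proximal_pos, model.distal_pos, model.decoy_pos) + 200
    seq = list(rng.choice(list("ACGT"), size=length))
    for site in (model.proximal_pos, model.distal_pos):
        # polyA-signal hexamer ~25-30 nt upstream of the cleavage site
        seq[site - signal_offset : site - signal_offset + 6] = "AATAAA"
        # non-A-rich downstream context, wide enough to cover jittered peaks
        seq[site : site + 25] = _NON_A_PATTERN[:25]
    d = model.decoy_pos
    seq[d : d + 25] = "A" * 25  # genomic A-tract the oligo-dT can prime on
    # scrub any accidental signal hexamer from the decoy's upstream window
    window_start = max(0, d - 50)
    scrub = "".join(seq[window_start:d])
    for hex_ in ("AATAAA", "ATTAAA"):
        idx = scrub.find(hex_)
        while idx != -1:
            seq[window_start + idx + 2] = "C"
            scrub = "".join(seq[window_start:d])
            idx = scrub.find(hex_)
    return "".join(seq)


def gen_three_prime_reads(
    gene_models: Optional[Sequence[GeneModel]] = None,
    usage: Optional[Dict[str, float]] = None,
    depth: int = 1_000,
    n_replicates: int = 2,
    jitter_sd: float = 5.0,
    ip_rate: float = 0.2,
    seed: int = 0,
    tolerance: int = 50,
):
    """3'-seq reads for two-polyA-site genes with internal-priming artifacts.

    ``usage`` maps condition -> expected proximal-site usage fraction
    (default WT 0.02, DKO 0.50, the Mbd2-like shift).  ``depth`` reads
    are drawn per condition, split evenly over ``n_replicates`` samples
    named ``<condition>_<rep>``.  A fraction ``ip_rate`` of reads is
    placed at the gene's A-tract decoy instead of a true site; cleavage
    positions get Gaussian positional jitter.  Genes live on '+' mRNA
    strand, so emitted alignments are '-' stranded with the 5' end at the
    cleavage position.  Returns (reads, genome dict, gene models).
    """
    if gene_models is None:
        gene_models = [GeneModel("geneA")]
    if usage is None:
        usage = {"WT": 0.02, "DKO": 0.50}
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0 <= ip_rate <= 1:
        raise ValueError("ip_rate must lie in [0, 1]")
    for m in gene_models:
        gap = abs(m.distal_pos - m.proximal_pos)
        if gap < 3 * tolerance:
            raise ValueError(
                f"{m.gene_id}: polyA sites {gap} nt apart; need >= 3x tolerance "
                f"({3 * tolerance} nt) for unambiguous clustering"
            )
        for f in usage.values():
            if not 0 <= f <= 1:
                raise ValueError("usage fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genome = {m.chrom: _build_chromosome(m, rng) for m in gene_models}
    reads: List[ThreePrimeRead] = []
    per_rep = [depth // n_replicates] * n_replicates
    per_rep[0] += depth - sum(per_rep)
    for model in gene_models:
        for cond in sorted(usage):
            prox_frac = usage[cond]
            for rep, n_reads in enumerate(per_rep, start=1):
                sample = f"{cond}_{rep}"
                for _ in range(n_reads):
                    if rng.random() < ip_rate:
                        site = model.decoy_pos
                    elif rng.random() < prox_frac:
                        site = model.proximal_pos
                    else:
                        site = model.distal_pos
                    pos = site + int(round(rng.normal(0, jitter_sd))) if jitter_sd > 0 else site
                    pos = max(1, min(pos, len(genome[model.chrom])))
                    reads.append(ThreePrimeRead(model.chrom, "-", pos, sample))
    return reads, genome, list(gene_models)


def write_reads_bed(reads: Sequence[ThreePrimeRead], path) -> None:
    """Write reads as BED6 single-base intervals at the alignment 5' end."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.five_prime_pos - 1}\t{r.five_prime_pos}\t"
                f"{r.sample_id}\t0\t{r.alignment_strand}\n"
            )


def write_genome_fasta(genome: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI tables with planted differential events

def gen_psi_table(
    n_events: int = 100,
    n_diff: Optional[int] = None,
    dpsi_choices: Sequence[float] = (20.0,),
    n_replicates: int = 2,
    noise_sd: float = 3.0,
    coverage_probs: Optional[Dict[str, float]] = None,
    seed: int = 0,
):
    """Event x sample PSI table with planted KO-vs-WT delta-PSI events.

    The first ``n_diff`` events receive a planted shift whose magnitude
    is drawn from ``dpsi_choices`` and whose sign is random; the rest are
    null.  Per-sample PSI = baseline (+ shift for KO samples) + Gaussian
    noise, clipped to [0, 100].  Coverage scores are sampled from
    ``coverage_probs`` (default: all 'OK').  Defaults mirror a 2-vs-2
    replicate design.  Returns (table DataFrame, ground-truth Series of
    signed planted delta-PSI per event).
    """
    if n_replicates < 1:
        raise ValueError("replicate count must be >= 1")
    if n_diff is None:
        n_diff = n_events // 2
    if not 0 <= n_diff <= n_events:
        raise ValueError("n_diff must lie in [0, n_events]")
    rng = np.random.default_rng(seed)
    if coverage_probs is None:
        coverage_probs = {"OK": 1.0}
    labels = list(coverage_probs)
    probs = np.array([coverage_probs[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    samples = [f"KO_{i}" for i in range(1, n_replicates + 1)] + [
        f"WT_{i}" for i in range(1, n_replicates + 1)
    ]
    rows = []
    truth = {}
    max_dpsi = max(abs(d) for d in dpsi_choices) if dpsi_choices else 0.0
    for ei in range(n_events):
        event = f"ev{ei:04d}"
        base = rng.uniform(10 + max_dpsi, 90 - max_dpsi)
        if ei < n_diff:
            dpsi = float(rng.choice(dpsi_choices)) * (1 if rng.random() < 0.5 else -1)
        else:
            dpsi = 0.0
        truth[event] = dpsi
        psis = {}
        for s in samples:
            shift = dpsi if s.startswith("KO") else 0.0
            noise = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
            psis[s] = float(np.clip(base + shift + noise, 0, 100))
        row = {
            "event_id": event,
            "gene": f"gene{ei:04d}",
            "chrom": "chr1",
            "span": f"{1000 * ei + 1}-{1000 * ei + 150}",
        }
        row.update({f"psi.{s}": psis[s] for s in samples})
        row.update({f"q.{s}": labels[rng.choice(len(labels), p=probs)] for s in samples})
        rows.append(row)
    return pd.DataFrame(rows), pd.Series(truth, name="planted_dpsi")


# ---------------------------------------------------------------------------
# TPM matrices with planted tissue-enriched genes

def gen_expression_matrix(
    n_genes: int = 200,
    n_enriched: int = 10,
    groups: Optional[Dict[str, int]] = None,
    target_group: str = "placenta",
    enrichment_log2fc: float = 3.0,
    base_tpm_mean: float = 30.0,
    noise_cv: float = 0.2,
    seed: int = 0,
):
    """Gene x sample TPM matrix with planted target-tissue-enriched genes.

    ``groups`` maps tissue group -> number of samples (default: placenta
    plus four somatic tissue groups, 2 samples each).  The first
    ``n_enriched`` genes are boosted ``enrichment_log2fc`` log2 units in
    the target group; all values get multiplicative lognormal noise with
    coefficient of variation ``noise_cv`` (0 disables noise).  Returns
    (tpm DataFrame, sample->group Series, set of planted gene ids).
    """
    if n_enriched > n_genes:
        raise ValueError("n_enriched cannot exceed n_genes")
    if groups is None:
        groups = {target_group: 2, "brain": 2, "liver": 2, "muscle": 2, "kidney": 2}
    if target_group not in groups:
        raise ValueError(f"target group {target_group!r} missing from groups")
    rng = np.random.default_rng(seed)
    genes = [f"sf{gi:04d}" for gi in range(n_genes)]
    planted = set(genes[:n_enriched])
    samples, labels = [], []
    for group in sorted(groups):
        for rep in range(1, groups[group] + 1):
            samples.append(f"{group}_{rep}")
            labels.append(group)
    base = rng.lognormal(np.log(base_tpm_mean), 0.5, size=n_genes)
    data = np.empty((n_genes, len(samples)))
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    for si, (sample, group) in enumerate(zip(samples, labels)):
        mean = base.copy()
        if group == target_group:
            mean[:n_enriched] *= 2.0**enrichment_log2fc
        noise = rng.lognormal(-sigma**2 / 2, sigma, size=n_genes) if sigma > 0 else 1.0
        data[:, si] = mean * noise
    tpm = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples)
    return tpm, pd.Series(labels, index=samples, name="group"), planted


def write_expression_matrix(tpm: pd.DataFrame, groups: pd.Series, path) -> None:
    """Write a TPM matrix TSV with a ``#group`` header row under the samples."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(tpm.columns) + "\n")
        fh.write("#group\t" + "\t".join(groups.loc[tpm.columns]) + "\n")
        tpm.to_csv(fh, sep="\t", header=False)
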