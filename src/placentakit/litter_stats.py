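"""Litter-aware statistics for placenta and embryo weights.

A litter (the conceptuses of one pregnancy) is the exchangeable unit for
genotype comparisons: between-litter weight variability is large, so
genotype labels are only exchangeable within litters.  This module
provides

* effective-genotype assignment, including the parental-origin rule for
  X-linked genes that are paternally silenced in placenta (a female
  heterozygote with a WT maternal allele is effectively WT; with a KO
  maternal allele it is effectively KO in placental tissue),
* a within-litter rank permutation test (each weight is ranked within
  its litter; the statistic is the summed KO rank-sum over litters;
  genotype labels are permuted independently within each litter),
* within-litter normalization (weight divided by the average of the
  litter's mean WT and mean KO weight),
* placental efficiency (embryo weight / placenta weight), and
* a two-sided Wilcoxon rank-sum comparison (exact by mid-rank
  enumeration for small samples).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TISSUES = ("placenta", "embryo")

__all__ = [
    "WeightRecord",
    "PermutationResult",
    "read_weights_table",
    "effective_genotype",
    "assign_effective_genotypes",
    "litter_rank_permutation_test",
    "normalize_within_litter",
    "placental_efficiency",
    "efficiency_table",
    "rank_sum_compare",
]


@dataclass
class WeightRecord:
    """One weighed specimen tissue (placenta or embryo)."""

    litter_id: str
    specimen_id: str
    tissue: str
    weight: float  # grams, > 0
    maternal_allele: Optional[str] = None  # '+' or '-'
    paternal_allele: Optional[str] = None
    sex: str = "unknown"  # 'F', 'M' or 'unknown'
    effective_genotype: Optional[str] = None  # 'WT', 'KO' or 'excluded'

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if not self.weight > 0:
            raise ValueError("weight must be > 0")


@dataclass
class PermutationResult:
    """Outcome of the within-litter rank permutation test.

    ``p`` is ``n_as_extreme / n_iter`` by default, or the smoothed
    ``(n_as_extreme + 1) / (n_iter + 1)`` when requested.  For exact
    enumeration ``n_iter`` is the number of distinct label arrangements.
    """

    observed_stat: float
    n_iter: int
    n_as_extreme: int
    p: float
    seed: Optional[int]
    method: str  # 'exact' or 'monte_carlo'
    alternative: str
    n_litters_used: int
    dropped_litters: tuple = ()


def read_weights_table(path) -> pd.DataFrame:
    """Read a weight TSV.

    Columns: ``litter_id specimen_id tissue weight_g gene maternal_allele
    paternal_allele sex`` with an optional precomputed
    ``effective_genotype`` column.  Weights are renamed to ``weight`` (grams).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"litter_id": str,
                                                         "specimen_id": str})
    if "weight_g" in df.columns:
        df = df.rename(columns={"weight_g": "weight"})
    required = {"litter_id", "specimen_id", "tissue", "weight"}
    if not required <= set(df.columns):
        raise ValueError(f"weight table needs columns {sorted(required)}")
    if not (df["weight"] > 0).all():
        raise ValueError("weights must be > 0")
    if df.duplicated(["litter_id", "specimen_id", "tissue"]).any():
        raise ValueError("(litter, specimen, tissue) keys must be unique")
    return df


def effective_genotype(
    maternal_allele: Optional[str],
    paternal_allele: Optional[str],
    sex: str = "unknown",
    x_linked: bool = True,
    context: str = "constitutive",
) -> str:
    """Collapse a raw allele pair into an effective WT/KO/excluded call.

    For X-linked, placentally imprinted genes (e.g. Mbnl3, expressed
    almost exclusively from the maternal allele in placenta):

    * female '+'(mat) / '-'(pat) -> WT (the expressed maternal allele is WT);
    * female '-'(mat) / '+'(pat) -> KO in the 'placental' context (placenta
      effectively KO, embryo mosaic), 'excluded' in the 'constitutive' one;
    * males are hemizygous: the maternal allele decides;
    * homozygous animals are WT/KO regardless of context.

    For autosomal genes (e.g. Mbnl2) heterozygotes are treated as WT.
    Unresolvable genotypes return 'excluded'.
    """
    if context not in ("constitutive", "placental"):
        raise ValueError(f"unknown context {context!r}")
    alleles = (maternal_allele, paternal_allele)
    if x_linked:
        if maternal_allele is None:
            raise ValueError("X-linked genotype requires the parental origin of alleles")
        if sex == "M" or paternal_allele is None:
            # hemizygous: single (maternal) X
            return {"+": "WT", "-": "KO"}.get(maternal_allele, "excluded")
        if any(a not in ("+", "-") for a in alleles):
            return "excluded"
        if maternal_allele == paternal_allele:
            return "WT" if maternal_allele == "+" else "KO"
        if maternal_allele == "+":  # het with WT maternal allele
            return "WT"
        # maternal KO / paternal WT female: placenta effectively KO
        return "KO" if context == "placental" else "excluded"
    # autosomal
    if any(a not in ("+", "-") for a in alleles):
        return "excluded"
    if maternal_allele == "-" and paternal_allele == "-":
        return "KO"
    return "WT"  # homozygous WT or heterozygote


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([vars(r) for r in records])


def assign_effective_genotypes(
    records, x_linked: bool = True, context: str = "constitutive"
) -> pd.DataFrame:
    """Fill the ``effective_genotype`` column of a weight table."""
    df = _as_frame(records)
    df["effective_genotype"] = [
        effective_genotype(m, p, s, x_linked=x_linked, context=context)
        for m, p, s in zip(df["maternal_allele"], df["paternal_allele"], df["sex"])
    ]
    return df


def _litter_rank_data(df: pd.DataFrame):
    """Per-litter (ranks, n_ko) with mid-ranks for ties; KO-less litters dropped."""
    litters, dropped = [], []
    for litter_id, ldf in df.groupby("litter_id", sort=True):
        genos = ldf["effective_genotype"].to_numpy()
        if not (("KO" in genos) and ("WT" in genos)):
            dropped.append(litter_id)
            continue
        ranks = stats.rankdata(ldf["weight"].to_numpy())  # ascending, mid-ranks
        is_ko = genos == "KO"
        litters.append((ranks, is_ko))
    if dropped:
        logger.warning("dropped litters without both genotypes: %s", dropped)
    return litters, tuple(dropped)


def _exact_ko_ranksum_distribution(ranks: np.ndarray, n_ko: int) -> dict:
    """Distribution of the KO rank-sum over all C(n, n_ko) label placements.

    Ranks are doubled so mid-ranks stay integral; returns {2*stat: count}.
    """
    doubled = np.rint(2 * ranks).astype(int)
    dist: dict = {}
    for combo in itertools.combinations(range(len(doubled)), n_ko):
        s = int(doubled[list(combo)].sum())
        dist[s] = dist.get(s, 0) + 1
    return dist


def litter_rank_permutation_test(
    records,
    tissue: str,
    n_iter: int = 1000,
    seed: Optional[int] = None,
    alternative: str = "ko_heavier",
    exact: str = "auto",
    smooth: bool = False,
    exact_limit: int = 10**6,
) -> PermutationResult:
    """Within-litter rank permutation test for a genotype effect on weight.

    Weights are ranked within each litter (ascending, mid-ranks for ties)
    and the observed statistic is the total KO rank-sum across litters.
    Genotype labels are then permuted independently within each litter,
    preserving per-litter genotype counts, and the p-value is the
    fraction of permutations whose statistic is at least as extreme as
    the observed one in the stated direction ('ko_heavier': permuted
    statistic >= observed; 'ko_lighter': <=).  When the number of
    distinct label arrangements is at most ``exact_limit`` and
    ``exact='auto'`` (or 'on'), the exact permutation distribution is
    computed by convolving per-litter rank-sum distributions instead of
    sampling.
    """
    if alternative not in ("ko_heavier", "ko_lighter"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if exact not in ("auto", "on", "off"):
        raise ValueError(f"exact must be auto|on|off, got {exact!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    df = _as_frame(records)
    df = df[df["tissue"] == tissue]
    litters, dropped = _litter_rank_data(df)
    if not litters:
        raise ValueError(f"no litter contains both genotypes for tissue {tissue!r}")

    observed = float(sum(ranks[is_ko].sum() for ranks, is_ko in litters))
    n_arrangements = 1
    for ranks, is_ko in litters:
        n_arrangements *= math.comb(len(ranks), int(is_ko.sum()))

    use_exact = exact == "on" or (exact == "auto" and n_arrangements <= exact_limit)
    if use_exact:
        # convolve independent per-litter distributions (doubled-rank scale)
        total: dict = {0: 1}
        for ranks, is_ko in litters:
            part = _exact_ko_ranksum_distribution(ranks, int(is_ko.sum()))
            new: dict = {}
            for s1, c1 in total.items():
                for s2, c2 in part.items():
                    new[s1 + s2] = new.get(s1 + s2, 0) + c1 * c2
            total = new
        obs2 = int(round(2 * observed))
        if alternative == "ko_heavier":
            n_extreme = sum(c for s, c in total.items() if s >= obs2)
        else:
            n_extreme = sum(c for s, c in total.items() if s <= obs2)
        n_total = sum(total.values())
        p = (n_extreme + 1) / (n_total + 1) if smooth else n_extreme / n_total
        return PermutationResult(
            observed, n_total, n_extreme, p, seed, "exact", alternative,
            len(litters), dropped,
        )

    rng = np.random.default_rng(seed)
    eps = 1e-9
    n_extreme = 0
    for _ in range(n_iter):
        stat = 0.0
        for ranks, is_ko in litters:
            perm = rng.permutation(len(ranks))
            stat += ranks[perm[: int(is_ko.sum())]].sum()
        if alternative == "ko_heavier":
            n_extreme += stat >= observed - eps
        else:
            n_extreme += stat <= observed + eps
    p = (n_extreme + 1) / (n_iter + 1) if smooth else n_extreme / n_iter
    return PermutationResult(
        observed, n_iter, int(n_extreme), p, seed, "monte_carlo", alternative,
        len(litters), dropped,
    )


def normalize_within_litter(
    records, tissue: str, min_per_genotype: int = 3
) -> pd.DataFrame:
    """Normalize weights by the litter's average of mean WT and mean KO weight.

    normalized = weight / ((mean_WT + mean_KO) / 2), per litter.  Litters
    with fewer than ``min_per_genotype`` animals of either genotype are
    excluded and logged.  By construction, within every retained litter
    (mean normalized WT + mean normalized KO) / 2 == 1 exactly.
    """
    df = _as_frame(records)
    df = df[df["tissue"] == tissue].copy()
    kept = []
    for litter_id, ldf in df.groupby("litter_id", sort=True):
        wt = ldf.loc[ldf["effective_genotype"] == "WT", "weight"]
        ko = ldf.loc[ldf["effective_genotype"] == "KO", "weight"]
        if len(wt) < min_per_genotype or len(ko) < min_per_genotype:
            logger.info(
                "litter %s excluded: %d WT / %d KO (< %d per genotype)",
                litter_id, len(wt), len(ko), min_per_genotype,
            )
            continue
        denom = (wt.mean() + ko.mean()) / 2.0
        ldf = ldf.copy()
        ldf["normalized_weight"] = ldf["weight"] / denom
        kept.append(ldf)
    if not kept:
        raise ValueError("no litter passes the per-genotype minimum")
    return pd.concat(kept, ignore_index=True)


def placental_efficiency(embryo, placenta) -> float:
    """Embryo weight divided by placenta weight for one specimen (unitless)."""
    if embryo.specimen_id != placenta.specimen_id:
        raise ValueError(
            f"specimen mismatch: {embryo.specimen_id!r} vs {placenta.specimen_id!r}"
        )
    if embryo.tissue != "embryo" or placenta.tissue != "placenta":
        raise ValueError("expected one embryo record and one placenta record")
    if not placenta.weight > 0:
        raise ValueError("placenta weight must be > 0")
    return embryo.weight / placenta.weight


def efficiency_table(records) -> pd.DataFrame:
    """Per-specimen placental efficiency from a mixed-tissue weight table."""
    df = _as_frame(records)
    wide = df.pivot_table(
        index=["litter_id", "specimen_id"], columns="tissue", values="weight"
    )
    if "embryo" not in wide or "placenta" not in wide:
        raise ValueError("need both embryo and placenta weights")
    wide = wide.dropna(subset=["embryo", "placenta"])
    wide["efficiency"] = wide["embryo"] / wide["placenta"]
    return wide.reset_index()[["litter_id", "specimen_id", "efficiency"]]


def rank_sum_compare(group_a, group_b, exact_max_n: int = 20):
    """Two-sided Wilcoxon rank-sum test between two weight groups.

    For combined n <= ``exact_max_n`` the p-value is exact: all
    C(n, n_a) assignments of the pooled mid-ranks are enumerated and the
    two-sided p is the fraction with |W - E[W]| at least the observed
    deviation (correct under ties).  Larger samples use the tie-corrected
    normal approximation.  Returns (rank-sum statistic of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[: len(a)].sum())
    n, n_a = len(pooled), len(a)
    mean_w = n_a * (n + 1) / 2.0
    if n <= exact_max_n:
        dev = abs(w_obs - mean_w) - 1e-9
        n_extreme = 0
        n_total = 0
        for combo in itertools.combinations(range(n), n_a):
            w = ranks[list(combo)].sum()
            n_total += 1
            n_extreme += abs(w - mean_w) >= dev
        return w_obs, n_extreme / n_total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return w_obs, float(res.pvalue)
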