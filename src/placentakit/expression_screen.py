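"""Tissue-enrichment screen for splicing factors and KO-specific gene rules.

The screen asks which of a candidate list of splicing regulators are
enriched in a target tissue group (e.g. placenta or trophoblast) relative
to the rest of the body.  Expression is in TPM; per-gene tissue-group
means are computed first and the enrichment is the log2 fold change of
the target group mean over the unweighted average of the other group
means.  Lowly expressed genes (target mean TPM <= 10 by default) are
excluded.

Also provided: set-filter rules on differential-expression tables - the
"Mbnl3-specific" classification (significant in the M3KO and DKO
comparisons but not the M2KO one) and a relaxed candidate-gene selection
(raw P < 0.1 and |log2FC| > 0.1) used to feed enrichment tools.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence, Set, Tuple

import numpy as np
import pandas as pd

DE_COMPARISONS = ("M2KO", "M3KO", "DKO")

__all__ = [
    "DE_COMPARISONS",
    "read_expression_matrix",
    "group_means",
    "enrichment_scores",
    "pairwise_enrichment",
    "mbnl3_specific_genes",
    "relaxed_candidate_genes",
]


def read_expression_matrix(path) -> Tuple[pd.DataFrame, pd.Series]:
    """Read a TPM matrix TSV with a ``#group`` tissue-label row.

    Line 1: ``gene`` plus sample names; line 2: ``#group`` plus the
    tissue-group label of each sample; remaining lines: per-gene TPMs.
    Returns (gene x sample DataFrame, sample -> group Series).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_row = fh.readline().rstrip("\n").split("\t")
        if group_row[0] != "#group":
            raise ValueError("second line must be the '#group' tissue-label row")
        samples = header[1:]
        if len(group_row) - 1 != len(samples):
            raise ValueError("group row length does not match sample count")
        tpm = pd.read_csv(fh, sep="\t", header=None, index_col=0, names=["gene"] + samples)
    tpm.index.name = "gene"
    return tpm, pd.Series(group_row[1:], index=samples, name="group")


def _check_matrix(tpm: pd.DataFrame, groups: pd.Series) -> pd.Series:
    groups = pd.Series(groups)
    unmapped = set(tpm.columns) - set(groups.index)
    if unmapped:
        raise ValueError(f"samples without a tissue group: {sorted(unmapped)[:5]}")
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return groups.loc[tpm.columns]


def group_means(tpm: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene mean TPM for each tissue group (genes x groups)."""
    groups = _check_matrix(tpm, groups)
    return tpm.T.groupby(groups).mean().T


def enrichment_scores(
    tpm: pd.DataFrame,
    groups: pd.Series,
    target_group: str,
    min_tpm: float = 10.0,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Target-tissue enrichment per gene.

    Tissue-group means are computed first; the score is
    log2((target mean + eps) / (mean of the other groups' means + eps)),
    i.e. nonplacental tissues enter as an unweighted average of group
    means, not of samples.  Genes whose target-group mean TPM is
    <= ``min_tpm`` are excluded.  Returns a DataFrame indexed by gene
    with columns target_mean_tpm and log2fc, sorted by log2fc descending.
    """
    means = group_means(tpm, groups)
    if target_group not in means.columns:
        raise ValueError(f"target group {target_group!r} absent from grouping")
    if means.shape[1] < 2:
        raise ValueError("need at least two tissue groups")
    target = means[target_group]
    others = means.drop(columns=[target_group]).mean(axis=1)
    out = pd.DataFrame(
        {
            "target_mean_tpm": target,
            "log2fc": np.log2((target + eps) / (others + eps)),
        }
    )
    return out[out["target_mean_tpm"] > min_tpm].sort_values(
        "log2fc", ascending=False
    )


def pairwise_enrichment(
    tpm: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b_set: Sequence[str],
    eps: float = 0.01,
) -> pd.DataFrame:
    """log2FC of one group's mean versus the average of a set of groups' means.

    Used for comparisons like trophectoderm vs inner cell mass, or
    trophoblast stem cells vs the average of ESC and XEN stem cells.
    """
    means = group_means(tpm, groups)
    missing = ({group_a} | set(group_b_set)) - set(means.columns)
    if missing:
        raise ValueError(f"groups absent from matrix: {sorted(missing)}")
    a = means[group_a]
    b = means[list(group_b_set)].mean(axis=1)
    return pd.DataFrame(
        {"group_a_mean_tpm": a, "log2fc": np.log2((a + eps) / (b + eps))}
    ).sort_values("log2fc", ascending=False)


def _pivot_de(de: pd.DataFrame, value: str) -> pd.DataFrame:
    required = {"comparison", "gene", value}
    if not required <= set(de.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    return de.pivot_table(index="gene", columns="comparison", values=value)


def mbnl3_specific_genes(de: pd.DataFrame, padj_threshold: float = 0.05) -> Set[str]:
    """Genes responding to Mbnl3 loss but not Mbnl2 loss.

    Selected: padj < threshold in both the M3KO and DKO comparisons AND
    padj >= threshold in the M2KO one.  ``de`` is a long-format table
    with columns (comparison, gene, log2fc, padj) covering all three
    comparisons.
    """
    if de.empty:
        return set()
    padj = _pivot_de(de, "padj")
    missing = set(DE_COMPARISONS) - set(padj.columns)
    if missing:
        raise ValueError(f"missing comparisons: {sorted(missing)}")
    sig = padj < padj_threshold
    mask = sig["M3KO"] & sig["DKO"] & ~sig["M2KO"] & padj["M2KO"].notna()
    return set(padj.index[mask.fillna(False)])


def relaxed_candidate_genes(
    de: pd.DataFrame,
    p_threshold: float = 0.1,
    min_abs_log2fc: float = 0.1,
) -> Tuple[Set[str], Set[str]]:
    """Up/down candidate gene sets under relaxed cutoffs.

    Applied to one comparison's table with columns (gene, log2fc, pvalue):
    keep genes with raw P < ``p_threshold`` AND |log2FC| > ``min_abs_log2fc``
    (both strict), then split by the sign of log2FC.
    """
    required = {"gene", "log2fc", "pvalue"}
    if not required <= set(de.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    sel = de[(de["pvalue"] < p_threshold) & (de["log2fc"].abs() > min_abs_log2fc)]
    up = set(sel.loc[sel["log2fc"] > 0, "gene"])
    down = set(sel.loc[sel["log2fc"] < 0, "gene"])
    return up, down
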