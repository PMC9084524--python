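"""Relative usage of competing splice donors as a transcription-start-site proxy.

Alternative promoters of a gene often splice from distinct 5' donors onto
one shared reference acceptor.  Counting RNA-seq reads over those
competing exon-exon junctions therefore quantifies relative promoter
usage without CAGE data.  Donors are annotated by the evolutionary origin
of their associated TSS (ancestral long-isoform, ancestral with first
coding exon skipped, eutherian-specific, or lineage-specific), and usage
is summarised as the percent of junction reads per donor class within
each sample group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

DONOR_CLASSES = (
    "ancestral_long",
    "ancestral_short_skip",
    "eutherian_specific",
    "lineage_specific",
)

__all__ = [
    "DONOR_CLASSES",
    "JunctionCountTable",
    "read_junction_table",
    "read_donor_annotation",
    "read_sample_groups",
    "load_packaged_donor_annotation",
    "donor_class_percent",
]


@dataclass
class JunctionCountTable:
    """Per-sample read counts over competing splice donors.

    ``records`` has columns sample_id, donor_id, acceptor_id, count;
    (sample_id, donor_id) pairs are unique and counts are non-negative.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        cols = ["sample_id", "donor_id", "acceptor_id", "count"]
        df = self.records.reindex(columns=cols).copy()
        df["count"] = df["count"].astype(int)
        if (df["count"] < 0).any():
            raise ValueError("negative junction counts")
        if df.duplicated(["sample_id", "donor_id"]).any():
            dup = df[df.duplicated(["sample_id", "donor_id"])].iloc[0]
            raise ValueError(
                f"duplicate (sample, donor) pair: ({dup.sample_id}, {dup.donor_id})"
            )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)


def read_junction_table(path) -> JunctionCountTable:
    """Parse a tab-separated ``sample_id donor_id acceptor_id count`` file.

    Lines starting with ``#`` are comments.  Duplicated (sample, donor)
    keys and malformed lines raise with the offending line number.
    """
    rows = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            sample, donor, acceptor, count_s = fields
            try:
                count = int(count_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer count {count_s!r}")
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if (sample, donor) in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate (sample, donor) pair ({sample}, {donor})"
                )
            seen.add((sample, donor))
            rows.append((sample, donor, acceptor, count))
    return JunctionCountTable(
        pd.DataFrame(rows, columns=["sample_id", "donor_id", "acceptor_id", "count"])
    )


def read_donor_annotation(path) -> pd.DataFrame:
    """Read a ``donor_id chrom pos class`` TSV (1-based positions)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["donor_id", "chrom", "pos", "class"],
        dtype={"donor_id": str, "chrom": str, "pos": int, "class": str},
    )
    bad = set(df["class"]) - set(DONOR_CLASSES)
    if bad:
        raise ValueError(f"unknown donor classes: {sorted(bad)}")
    return df.set_index("donor_id")


def read_sample_groups(path) -> pd.Series:
    """Read a ``sample_id group`` TSV into a sample -> group mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["sample_id", "group"], dtype=str)
    return df.set_index("sample_id")["group"]


def load_packaged_donor_annotation(species: str = "mouse") -> pd.DataFrame:
    """Load the packaged donor->class map for a species.

    The shipped maps are synthetic stand-ins that keep the published
    header scheme (numbered donors with X-chromosome coordinates); only
    the eutherian-specific donor coordinate printed for mouse
    (chrX:132413583, donor 3) is a real coordinate.
    """
    fname = f"{species}_tss_donor_classes.synthetic.tsv"
    ref = resources.files("placentakit.data").joinpath(fname)
    if not ref.is_file():
        raise ValueError(f"no packaged donor annotation for species {species!r}")
    with resources.as_file(ref) as p:
        return read_donor_annotation(p)


def donor_class_percent(
    counts,
    annotation: pd.DataFrame,
    grouping=None,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Percent of junction reads per donor class within each sample group.

    mode='pooled' (default) pools read counts across a group's samples
    before taking percentages, which is robust to low-coverage samples;
    mode='mean' averages per-sample percentages instead.  The two agree
    whenever all samples in a group have equal totals.  Groups with zero
    total reads yield NaN percents with a warning rather than silent 0s.
    """
    if mode not in ("pooled", "mean"):
        raise ValueError(f"mode must be 'pooled' or 'mean', got {mode!r}")
    if isinstance(counts, JunctionCountTable):
        df = counts.records.copy()
    else:
        df = pd.DataFrame(counts).copy()
    missing = set(df["donor_id"]) - set(annotation.index)
    if missing:
        raise ValueError(f"donors missing from annotation: {sorted(missing)[:5]}")
    df["class"] = annotation.loc[df["donor_id"], "class"].to_numpy()
    if grouping is None:
        df["group"] = df["sample_id"]
    else:
        grouping = pd.Series(grouping)
        unmapped = set(df["sample_id"]) - set(grouping.index)
        if unmapped:
            raise ValueError(f"samples missing from grouping: {sorted(unmapped)[:5]}")
        df["group"] = grouping.loc[df["sample_id"]].to_numpy()

    out = []
    for group, gdf in df.groupby("group", sort=True):
        if mode == "pooled":
            class_sums = gdf.groupby("class")["count"].sum()
            total = class_sums.sum()
            if total == 0:
                warnings.warn(f"group {group!r} has zero total junction reads")
                pct = pd.Series(float("nan"), index=DONOR_CLASSES)
            else:
                pct = class_sums.reindex(DONOR_CLASSES, fill_value=0) / total * 100.0
        else:
            per_sample = []
            for sample, sdf in gdf.groupby("sample_id"):
                class_sums = sdf.groupby("class")["count"].sum()
                total = class_sums.sum()
                if total == 0:
                    warnings.warn(f"sample {sample!r} has zero total junction reads")
                    continue
                per_sample.append(
                    class_sums.reindex(DONOR_CLASSES, fill_value=0) / total * 100.0
                )
            if not per_sample:
                warnings.warn(f"group {group!r} has no sample with junction reads")
                pct = pd.Series(float("nan"), index=DONOR_CLASSES)
            else:
                pct = pd.concat(per_sample, axis=1).mean(axis=1)
        for cls in DONOR_CLASSES:
            out.append((group, cls, float(pct[cls])))
    return pd.DataFrame(out, columns=["group", "class", "percent"])
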