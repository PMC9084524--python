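"""Coverage and delta-PSI filters for differential alternative splicing.

Exon inclusion is measured as percent spliced in (PSI, 0-100) per event
and sample, with an ordinal per-sample coverage score
(N < VLOW < LOW < OK < SOK).  An event is called differential between
two conditions when the mean PSI difference reaches ``dpsi_min`` (default
15 PSI points) and every replicate-level difference agrees in direction
by at least ``per_rep_min`` (default 5 points).  The same rule applied to
wild-type samples at two developmental stages defines developmental
events, against which KO shifts are summarised to quantify whether loss
of a regulator pushes the tissue toward an immature splicing state.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COVERAGE_LEVELS = ("N", "VLOW", "LOW", "OK", "SOK")
_COVERAGE_RANK = {label: i for i, label in enumerate(COVERAGE_LEVELS)}

__all__ = [
    "COVERAGE_LEVELS",
    "DiffExonCall",
    "read_psi_table",
    "write_psi_table",
    "coverage_filter",
    "call_differential",
    "call_developmental",
    "maturation_shift_summary",
    "overlap_counts",
]


@dataclass
class DiffExonCall:
    """A differential exon-inclusion call between two conditions."""

    event_id: str
    direction: str  # 'up' or 'down' (first condition relative to second)
    mean_dpsi: float
    min_pairwise_dpsi: float  # signed replicate difference closest to zero


def read_psi_table(path) -> pd.DataFrame:
    """Read an event x sample PSI table.

    Columns: ``event_id gene chrom span psi.<sample>... q.<sample>...``
    where q columns hold ordinal coverage scores.  PSI values must lie in
    [0, 100] and every psi column needs a matching q column.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    psi_cols = [c for c in df.columns if c.startswith("psi.")]
    q_cols = [c for c in df.columns if c.startswith("q.")]
    if {c[4:] for c in psi_cols} != {c[2:] for c in q_cols}:
        raise ValueError("psi.<sample> and q.<sample> columns must match")
    vals = df[psi_cols].to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 100:
        raise ValueError("PSI values must lie in [0, 100]")
    return df


def write_psi_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _samples(df: pd.DataFrame) -> List[str]:
    return [c[4:] for c in df.columns if c.startswith("psi.")]


def coverage_filter(df: pd.DataFrame, min_score: str = "LOW") -> pd.DataFrame:
    """Keep events whose coverage score is >= ``min_score`` in every sample.

    This mirrors a "no VLOW" quality rule: with the default, an event is
    dropped as soon as any sample scores N or VLOW.  Unknown score labels
    are a hard error, never silently mapped.
    """
    if min_score not in _COVERAGE_RANK:
        raise ValueError(f"unknown coverage score {min_score!r}")
    q_cols = [c for c in df.columns if c.startswith("q.")]
    scores = df[q_cols]
    unknown = set(scores.to_numpy().ravel()) - set(COVERAGE_LEVELS)
    if unknown:
        raise ValueError(f"unknown coverage score labels: {sorted(unknown)}")
    ranks = scores.apply(lambda col: col.map(_COVERAGE_RANK))
    keep = (ranks >= _COVERAGE_RANK[min_score]).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("coverage filter dropped %d/%d events", n_dropped, len(df))
    return df[keep].reset_index(drop=True)


def _evaluate_event(
    ko: np.ndarray, wt: np.ndarray, dpsi_min: float, per_rep_min: float, pairing: str
):
    """(direction, mean_dpsi, min_pairwise) or None for one event."""
    mean_d = float(ko.mean() - wt.mean())
    if pairing == "all_pairs":
        diffs = np.array([k - w for k in ko for w in wt])
    elif pairing == "by_index":
        if len(ko) != len(wt):
            raise ValueError("by_index pairing requires equal replicate counts")
        diffs = ko - wt
    else:
        raise ValueError(f"pairing must be all_pairs|by_index, got {pairing!r}")
    if mean_d >= dpsi_min and (diffs >= per_rep_min).all():
        return "up", mean_d, float(diffs.min())
    if mean_d <= -dpsi_min and (diffs <= -per_rep_min).all():
        return "down", mean_d, float(diffs.max())
    return None


def call_differential(
    df: pd.DataFrame,
    ko_samples: Sequence[str],
    wt_samples: Sequence[str],
    dpsi_min: float = 15.0,
    per_rep_min: float = 5.0,
    pairing: str = "all_pairs",
) -> List[DiffExonCall]:
    """Call differentially included exons between KO and WT samples.

    An event is 'up' when mean(KO) - mean(WT) >= ``dpsi_min`` AND every
    replicate-level KO-vs-WT difference is >= ``per_rep_min`` in the same
    direction ('down' symmetric).  With the default all-pairs pairing the
    replicate rule is equivalent to min(KO) - max(WT) >= per_rep_min,
    which is at least as strict as any index-based replicate pairing.
    """
    if not len(ko_samples) or not len(wt_samples):
        raise ValueError("need at least one sample per condition")
    missing = (set(ko_samples) | set(wt_samples)) - set(_samples(df))
    if missing:
        raise ValueError(f"samples missing from table: {sorted(missing)}")
    ko_cols = [f"psi.{s}" for s in ko_samples]
    wt_cols = [f"psi.{s}" for s in wt_samples]
    calls = []
    for _, row in df.iterrows():
        res = _evaluate_event(
            row[ko_cols].to_numpy(dtype=float),
            row[wt_cols].to_numpy(dtype=float),
            dpsi_min, per_rep_min, pairing,
        )
        if res is not None:
            calls.append(DiffExonCall(row["event_id"], *res))
    return calls


def call_developmental(
    df: pd.DataFrame,
    early_samples: Sequence[str],
    late_samples: Sequence[str],
    dpsi_min: float = 15.0,
    per_rep_min: float = 5.0,
    pairing: str = "all_pairs",
) -> List[DiffExonCall]:
    """Developmental exon calls: late-stage vs early-stage WT samples.

    'up' means inclusion increases with developmental time.
    """
    return call_differential(
        df, late_samples, early_samples, dpsi_min, per_rep_min, pairing
    )


def maturation_shift_summary(
    dev_calls: Sequence[DiffExonCall], ko_deltas: Dict[str, float]
) -> Dict[str, float]:
    """Summarise KO splicing shifts over developmentally regulated exons.

    ``ko_deltas`` maps event_id -> KO-vs-WT delta-PSI.  Returns the
    median KO delta over developmentally up- and down-regulated events
    and the fraction of developmental events whose KO shift opposes the
    developmental direction (an anti-maturation signature); zero KO
    deltas count as non-opposing.
    """
    if not dev_calls:
        raise ValueError("developmental call set is empty")
    missing = [c.event_id for c in dev_calls if c.event_id not in ko_deltas]
    if missing:
        raise ValueError(f"KO deltas missing for events: {missing[:5]}")
    up = [ko_deltas[c.event_id] for c in dev_calls if c.direction == "up"]
    down = [ko_deltas[c.event_id] for c in dev_calls if c.direction == "down"]
    n_oppose = sum(
        1
        for c in dev_calls
        if (c.direction == "up" and ko_deltas[c.event_id] < 0)
        or (c.direction == "down" and ko_deltas[c.event_id] > 0)
    )
    return {
        "median_ko_dpsi_dev_up": float(np.median(up)) if up else float("nan"),
        "median_ko_dpsi_dev_down": float(np.median(down)) if down else float("nan"),
        "fraction_opposing": n_oppose / len(dev_calls),
    }


def overlap_counts(call_sets: Dict[str, Iterable[str]]) -> Dict[Tuple[str, ...], int]:
    """Exclusive Venn-region counts for >= 2 named call sets.

    Keys are sorted tuples of set names; the value is the number of
    elements in exactly those sets.  Region counts sum to |union|.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets")
    sets = {name: set(s) for name, s in call_sets.items()}
    names = sorted(sets)
    regions: Dict[Tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            regions[combo] = len(inside - outside)
    return regions
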