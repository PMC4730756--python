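"""Enumeration of ganglion bipartitions and the three-criterion marker filter.

Every non-empty proper subset of the ganglion labels is a candidate "high"
group (2^n - 2 groupings for n labels).  A gene is a marker candidate for a
grouping when it satisfies all three study criteria:

1. **dominance** — expression at least ``fold_threshold`` (default 1.5x)
   higher in *every* high-group sample than in *every* low-group sample,
   evaluated on RPKM: ``min(high) >= fold * max(low)``;
2. **floor** — RPKM of at least ``min_high_rpkm`` (default 10) in every
   high-group sample;
3. **consensus DE** — called up-in-high by both NB engines at
   ``q <= q_threshold`` (default 0.05).

A gene passing for several groupings is assigned to exactly one: the most
specific (smallest high set), breaking ties by larger dominance ratio and
then by grouping id.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Grouping:
    """A high/low bipartition of the ganglion labels."""

    high: frozenset
    low: frozenset

    def __post_init__(self):
        if not self.high or not self.low:
            raise ValueError("both sides of a grouping must be non-empty")
        if self.high & self.low:
            raise ValueError("high and low sets overlap")

    @property
    def id(self) -> str:
        """Canonical id, e.g. ``'N,P|Top,Tmm,VA'`` (each side sorted)."""
        return ",".join(sorted(self.high)) + "|" + ",".join(sorted(self.low))

    @classmethod
    def from_id(cls, gid: str) -> "Grouping":
        hi, lo = gid.split("|")
        return cls(frozenset(hi.split(",")), frozenset(lo.split(",")))

    @classmethod
    def from_high(cls, high, all_labels) -> "Grouping":
        high = frozenset(high)
        return cls(high, frozenset(all_labels) - high)


def enumerate_groupings(labels) -> list[Grouping]:
    """All 2^n - 2 high/low bipartitions, smallest high sets first.

    Deterministic order: by high-set size, then lexicographically by the
    sorted high labels.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 ganglion labels to form groupings")
    if len(set(labels)) != len(labels):
        raise ValueError("ganglion labels must be unique")
    out = []
    for k in range(1, len(labels)):
        for combo in sorted(combinations(sorted(labels), k)):
            out.append(Grouping.from_high(combo, labels))
    return out


def dominance_pass(
    rpkm_row: np.ndarray,
    high_idx: np.ndarray,
    low_idx: np.ndarray,
    fold: float = 1.5,
) -> tuple[bool, float]:
    """Per-sample dominance: ``min(high RPKM) >= fold * max(low RPKM)``.

    Returns the pass flag and the dominance ratio ``min(high)/max(low)``
    (``inf`` when the low maximum is 0 and the high minimum positive).
    """
    row = np.asarray(rpkm_row, dtype=float)
    hi_min = row[high_idx].min()
    lo_max = row[low_idx].max()
    if lo_max == 0:
        return (hi_min > 0), float("inf") if hi_min > 0 else 0.0
    ratio = hi_min / lo_max
    return ratio >= fold, float(ratio)


def rpkm_floor_pass(
    rpkm_row: np.ndarray, high_idx: np.ndarray, min_rpkm: float = 10.0
) -> bool:
    """Every high-group sample at or above the RPKM floor (inclusive)."""
    return bool(np.asarray(rpkm_row, dtype=float)[high_idx].min() >= min_rpkm)


def select_markers(
    de_by_grouping: dict[str, pd.DataFrame],
    rpkm: pd.DataFrame,
    sample_labels: pd.Series,
    config,
) -> pd.DataFrame:
    """Apply the three-criterion filter and assign each gene one grouping.

    Parameters
    ----------
    de_by_grouping : dict
        Grouping id -> per-gene DE table with a boolean ``consensus`` column
        and ``q_exact`` / ``q_glm`` columns (from
        :func:`ganglimark.diffexp.de_for_grouping`).
    rpkm : DataFrame
        Gene x sample RPKM matrix.
    sample_labels : Series
        Sample id -> ganglion label, aligned with ``rpkm`` columns.
    config : PipelineConfig
        Supplies ``fold_threshold``, ``min_high_rpkm`` and ``q_threshold``.

    Returns
    -------
    DataFrame indexed by gene with columns ``grouping``, ``dominance_ratio``,
    ``min_high_rpkm``, ``q_exact``, ``q_glm``; each gene appears once.
    """
    labels = sample_labels.loc[rpkm.columns]
    candidates: dict[str, list[tuple]] = {}
    for gid, de in de_by_grouping.items():
        grouping = Grouping.from_id(gid)
        high_idx = np.flatnonzero(labels.isin(grouping.high).to_numpy())
        low_idx = np.flatnonzero(labels.isin(grouping.low).to_numpy())
        cons_genes = de.index[de["consensus"].astype(bool)]
        for gene in cons_genes:
            row = rpkm.loc[gene].to_numpy(dtype=float)
            ok_dom, ratio = dominance_pass(row, high_idx, low_idx, config.fold_threshold)
            if not ok_dom:
                continue
            if not rpkm_floor_pass(row, high_idx, config.min_high_rpkm):
                continue
            candidates.setdefault(gene, []).append(
                (
                    len(grouping.high),
                    -ratio if np.isfinite(ratio) else -np.inf,
                    gid,
                    float(row[high_idx].min()),
                    float(de.at[gene, "q_exact"]),
                    float(de.at[gene, "q_glm"]),
                    ratio,
                )
            )
    records = []
    for gene, opts in candidates.items():
        # most specific grouping first; ties -> larger dominance, then id
        size, _, gid, min_hi, qe, qg, ratio = sorted(opts)[0]
        records.append((gene, gid, ratio, min_hi, qe, qg))
    out = pd.DataFrame(
        records,
        columns=["gene", "grouping", "dominance_ratio", "min_high_rpkm",
                 "q_exact", "q_glm"],
    ).set_index("gene")
    return out.sort_values(["grouping", "dominance_ratio"],
                           ascending=[True, False])


def summarize_marker_counts(marker_table: pd.DataFrame) -> pd.DataFrame:
    """Markers per grouping plus a grand total; empty groupings omitted."""
    if len(marker_table) == 0:
        return pd.DataFrame(columns=["grouping", "n_markers"]).set_index("grouping")
    counts = marker_table.groupby("grouping").size().sort_values(ascending=False)
    summary = counts.to_frame("n_markers")
    summary.loc["TOTAL"] = len(marker_table)
    return summary
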