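"""Core tabular containers shared by every pipeline stage.

All three input tables are held as validated pandas objects: a gene x sample
integer count matrix, a per-sample design table (ganglion label, replicate,
optional technical covariates) and a per-gene annotation table (length in bp,
optional term identifiers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

#: covariate columns recognised in a design table, beyond label/replicate
KNOWN_COVARIATES = ("rin", "rna_yield_ng", "read_depth")


class CountMatrix:
    """Non-negative integer gene x sample expression counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Genes in rows, samples in columns.  Index and columns must be
        unique; every entry must be a non-negative integer.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_bad_entry(counts, lambda v: not _is_count(v))
            raise ValueError(f"non-integer count at gene {bad[0]!r}, sample {bad[1]!r}")
        if np.any(arr != np.floor(arr)) or np.any(np.isnan(arr)):
            bad = _first_bad_entry(counts, lambda v: not _is_count(v))
            raise ValueError(f"non-integer count at gene {bad[0]!r}, sample {bad[1]!r}")
        if (arr < 0).any():
            bad = _first_bad_entry(counts, lambda v: v < 0)
            raise ValueError(f"negative count at gene {bad[0]!r}, sample {bad[1]!r}")
        self.counts = counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> pd.Series:
        """Raw per-sample column sums."""
        return self.counts.sum(axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


def _is_count(v) -> bool:
    try:
        return float(v) == int(float(v)) and float(v) >= 0
    except (TypeError, ValueError):
        return False


def _first_bad_entry(df: pd.DataFrame, pred):
    for g in df.index:
        for s in df.columns:
            if pred(df.at[g, s]):
                return g, s
    raise AssertionError("no offending entry found")


class SampleDesign:
    """Sample-to-ganglion assignment with replicate numbers and covariates.

    The design table is indexed by sample id and has at least the columns
    ``ganglion`` and ``replicate``; any numeric extra column is treated as a
    technical covariate (e.g. ``rin``, ``rna_yield_ng``, ``read_depth``).
    """

    def __init__(self, table: pd.DataFrame):
        if "ganglion" not in table.columns or "replicate" not in table.columns:
            raise ValueError("design table needs 'ganglion' and 'replicate' columns")
        if table.index.duplicated().any():
            dup = table.index[table.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in design: {dup!r}")
        if (table["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        self.table = table.copy()
        self.table["replicate"] = self.table["replicate"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def labels(self) -> list[str]:
        """Ganglion labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.table["ganglion"]:
            seen.setdefault(lab, None)
        return list(seen)

    def samples_for(self, label: str) -> list[str]:
        return list(self.table.index[self.table["ganglion"] == label])

    def covariates(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c not in ("ganglion", "replicate")]
        return self.table[cols].astype(float)

    def validate_against(self, cm: CountMatrix) -> None:
        """Check design/counts cross-references and replication.

        Every sample in the count matrix must appear exactly once in the
        design, and every ganglion label needs at least two samples (the
        dispersion estimate and both DE engines require replication).
        """
        for s in cm.sample_ids:
            if s not in self.table.index:
                raise ValueError(f"sample {s!r} missing from design table")
        extra = set(self.table.index) - set(cm.sample_ids)
        if extra:
            raise ValueError(f"design sample(s) absent from counts: {sorted(extra)}")
        sizes = self.table["ganglion"].value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise ValueError(
                f"ganglion group(s) with <2 replicates: {sorted(small.index)}"
            )


class GeneAnnotation:
    """Per-gene lengths (bp) and optional term identifiers.

    ``table`` is indexed by gene id with a ``length_bp`` column and an
    optional ``terms`` column holding semicolon-separated term ids.
    """

    def __init__(self, table: pd.DataFrame):
        if "length_bp" not in table.columns:
            raise ValueError("annotation table needs a 'length_bp' column")
        if table.index.duplicated().any():
            dup = table.index[table.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in annotation: {dup!r}")
        if (table["length_bp"].astype(float) <= 0).any():
            bad = table.index[table["length_bp"].astype(float) <= 0][0]
            raise ValueError(f"non-positive gene length for {bad!r}")
        self.table = table.copy()
        self.table["length_bp"] = self.table["length_bp"].astype(int)

    def lengths_for(self, gene_ids) -> pd.Series:
        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise ValueError(f"gene(s) missing from annotation: {missing[:5]}")
        return self.table.loc[gene_ids, "length_bp"]

    def term_map(self) -> dict[str, set[str]]:
        """gene id -> set of term ids (genes with no terms omitted)."""
        out: dict[str, set[str]] = {}
        if "terms" not in self.table.columns:
            return out
        for g, raw in self.table["terms"].items():
            if isinstance(raw, str) and raw.strip():
                out[g] = {t for t in raw.split(";") if t}
        return out


@dataclass
class PipelineConfig:
    """Thresholds and run parameters for the whole pipeline.

    Defaults encode the study's published criteria: a 1.5-fold per-sample
    dominance requirement, a minimum RPKM of 10 in every high-group sample,
    consensus FDR q <= 0.05 from both DE engines, and an expressed-gene
    threshold of 0.3 RPKM.
    """

    fold_threshold: float = 1.5
    min_high_rpkm: float = 10.0
    q_threshold: float = 0.05
    expressed_rpkm_threshold: float = 0.3
    bootstrap_scales: tuple = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))
    nboot: int = 1000
    seed: int = 0
    enrichment_q_threshold: float = 0.05

    def __post_init__(self):
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        for name in ("min_high_rpkm", "expressed_rpkm_threshold",
                     "enrichment_q_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # q_threshold = 0 is allowed as a degenerate setting (no consensus
        # calls can pass), useful for negative controls
        if self.q_threshold < 0:
            raise ValueError("q_threshold must be >= 0")
        scales = tuple(float(r) for r in self.bootstrap_scales)
        if any(r <= 0 for r in scales):
            raise ValueError("bootstrap scales must all be > 0")
        if not any(abs(r - 1.0) < 1e-9 for r in scales):
            raise ValueError("bootstrap scales must include 1.0")
        self.bootstrap_scales = scales
        if self.nboot < 1:
            raise ValueError("nboot must be positive")

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "PipelineConfig":
        """Build a config from a flat mapping, filling defaults for
        missing keys and rejecting unknown ones."""
        mapping = dict(mapping or {})
        valid = {f.name for f in fields(cls)}
        unknown = set(mapping) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["bootstrap_scales"] = list(d["bootstrap_scales"])
        return d
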