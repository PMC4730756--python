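"""Reading and writing the pipeline's tabular formats.

All artifacts are TSV with a header row; counts have gene rows and sample
columns.  Configuration is flat YAML mirroring
:class:`~ganglimark.containers.PipelineConfig`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from ganglimark.containers import (
    CountMatrix,
    GeneAnnotation,
    PipelineConfig,
    SampleDesign,
)


def read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def read_design(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t", index_col=0))


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "terms" in df.columns:
        df["terms"] = df["terms"].fillna("")
    return GeneAnnotation(df)


def read_config(path=None, **overrides) -> PipelineConfig:
    """Load a flat YAML config; missing keys fall back to defaults and
    keyword overrides (e.g. CLI flags) win over file values."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig.from_mapping(data)


def read_inputs(
    counts_path, design_path, annotation_path, config_path=None
) -> tuple[CountMatrix, SampleDesign, GeneAnnotation, PipelineConfig]:
    """Read and cross-validate the full input set."""
    cm = read_counts(counts_path)
    design = read_design(design_path)
    annot = read_annotation(annotation_path)
    design.validate_against(cm)
    annot.lengths_for(cm.gene_ids)  # raises on missing genes
    cfg = read_config(config_path)
    return cm, design, annot, cfg


_FLOAT_FMT = "%.12g"  # 12 significant digits survive a round-trip


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_results(out_dir, artifacts: dict, config: PipelineConfig, version: str) -> dict:
    """Write all result tables plus a run manifest; returns the manifest.

    ``artifacts`` maps artifact name to either a DataFrame/Series (written
    as ``<name>.tsv``) or a string (written verbatim, e.g. Newick).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": version,
        "files": {},
        "n_markers": None,
    }
    for name, obj in artifacts.items():
        if isinstance(obj, str):
            path = out / f"{name}.newick" if "dendrogram" in name else out / f"{name}.txt"
            path.write_text(obj)
        else:
            if isinstance(obj, pd.Series):
                obj = obj.to_frame(name)
            path = out / f"{name}.tsv"
            write_table(obj, path)
        manifest["files"][name] = path.name
        if name == "markers":
            manifest["n_markers"] = int(len(obj))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
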