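"""End-to-end orchestration of the marker-discovery pipeline.

Stage order mirrors the study: normalise (two schemes) -> expressed-gene
report -> dispersion model -> consensus DE over every ganglion bipartition
-> three-criterion marker selection -> PCA with covariate screen -> marker
dendrogram with AU/BP support -> term enrichment of the marker set against
the expressed background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

import ganglimark
from ganglimark import diffexp, enrich, normalize, structure
from ganglimark.containers import (
    CountMatrix,
    GeneAnnotation,
    PipelineConfig,
    SampleDesign,
)
from ganglimark.markers import (
    enumerate_groupings,
    select_markers,
    summarize_marker_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    size_factors: pd.DataFrame
    rpkm: pd.DataFrame
    vst: pd.DataFrame
    expressed_per_sample: pd.Series
    expressed_union: list
    dispersion: "diffexp.DispersionModel"
    de_by_grouping: dict
    markers: pd.DataFrame
    marker_summary: pd.DataFrame
    pca: "structure.PCAResult"
    covariate_cor: pd.DataFrame
    dendrogram: "structure.DendrogramNode | None"
    node_support: pd.DataFrame
    enrichment: pd.DataFrame
    stages: list = field(default_factory=list)


def run_pipeline(
    cm: CountMatrix,
    design: SampleDesign,
    annot: GeneAnnotation,
    config: PipelineConfig,
) -> PipelineResult:
    """Run every stage on a validated input set."""
    design.validate_against(cm)
    stages = []

    def _stage(name, fn):
        logger.info("stage %s: starting", name)
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages.append(name)
        return out

    sf_exact = _stage("normalize/median_of_ratios",
                      lambda: normalize.size_factors_median_of_ratios(cm))
    sf_tmm = _stage("normalize/tmm", lambda: normalize.tmm_factors(cm))
    lengths = annot.lengths_for(cm.gene_ids)
    rpkm = _stage("normalize/rpkm", lambda: normalize.rpkm_matrix(cm, lengths))
    per_sample, union = _stage(
        "expressed_report",
        lambda: normalize.expressed_gene_report(rpkm, config.expressed_rpkm_threshold),
    )
    logger.info("expressed-gene report: union of %d genes above %.2f RPKM",
                len(union), config.expressed_rpkm_threshold)

    disp = _stage("dispersion",
                  lambda: diffexp.fit_dispersion_model(cm, sf_exact.factors, design))
    vst = _stage("normalize/vst",
                 lambda: normalize.vst_transform(cm, sf_exact, (disp.a0, disp.a1)))

    groupings = enumerate_groupings(design.labels)
    logger.info("testing %d ganglion bipartitions", len(groupings))
    de_by_grouping = {}
    for grouping in groupings:
        de_by_grouping[grouping.id] = _stage(
            f"de/{grouping.id}",
            lambda g=grouping: diffexp.de_for_grouping(
                cm, design, g.high, disp, sf_exact.factors, sf_tmm.factors,
                config.q_threshold,
            ),
        )
        n_cons = int(de_by_grouping[grouping.id]["consensus"].sum())
        logger.info("grouping %s: %d consensus DE genes", grouping.id, n_cons)

    labels = design.table["ganglion"]
    markers = _stage(
        "markers",
        lambda: select_markers(de_by_grouping, rpkm, labels, config),
    )
    summary = summarize_marker_counts(markers)
    logger.info("marker selection: %d markers across %d groupings",
                len(markers), markers["grouping"].nunique() if len(markers) else 0)

    pca = _stage("pca", lambda: structure.pca_samples(vst))
    covs = design.covariates()
    if covs.shape[1]:
        cov_cor = _stage(
            "covariate_screen",
            lambda: structure.pc_covariate_correlation(pca.scores, covs),
        )
    else:
        cov_cor = pd.DataFrame(
            columns=["component", "covariate", "r", "p", "undefined",
                     "p_adj", "significant"]
        )

    if len(markers) >= 2:
        dend, support = _stage(
            "dendrogram",
            lambda: structure.multiscale_bootstrap_support(
                vst.loc[markers.index],
                scales=config.bootstrap_scales,
                nboot=config.nboot,
                seed=config.seed,
            ),
        )
    else:
        logger.info("dendrogram skipped: fewer than 2 markers")
        dend, support = None, pd.DataFrame()

    term_map = annot.term_map()
    if len(markers) and term_map:
        enr = _stage(
            "enrichment",
            lambda: enrich.enrich_terms(
                [g for g in markers.index if g in set(union)],
                union,
                term_map,
                config.enrichment_q_threshold,
            ),
        )
    else:
        enr = pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q", "significant"])

    sf = pd.DataFrame(
        {"median_of_ratios": sf_exact.factors, "tmm": sf_tmm.factors}
    )
    return PipelineResult(
        size_factors=sf,
        rpkm=rpkm,
        vst=vst,
        expressed_per_sample=per_sample,
        expressed_union=union,
        dispersion=disp,
        de_by_grouping=de_by_grouping,
        markers=markers,
        marker_summary=summary,
        pca=pca,
        covariate_cor=cov_cor,
        dendrogram=dend,
        node_support=support,
        enrichment=enr,
        stages=stages,
    )


def result_artifacts(res: PipelineResult) -> dict:
    """Flatten a PipelineResult into writable named artifacts."""
    arts = {
        "size_factors": res.size_factors,
        "rpkm": res.rpkm,
        "vst": res.vst,
        "expressed_per_sample": res.expressed_per_sample.to_frame("n_expressed"),
        "markers": res.markers,
        "marker_summary": res.marker_summary,
        "pca_scores": res.pca.scores,
        "pca_variance": pd.DataFrame(
            {"variance_explained": res.pca.variance_explained},
            index=res.pca.scores.columns,
        ),
        "pc_covariate_cor": res.covariate_cor,
        "node_support": res.node_support,
        "enrichment": res.enrichment,
    }
    for gid, de in res.de_by_grouping.items():
        arts[f"de_{gid.replace('|', '_vs_').replace(',', '-')}"] = de
    if res.dendrogram is not None:
        arts["dendrogram"] = res.dendrogram.newick() + ";\n"
    return arts
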