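#!/usr/bin/env python
"""Normalise the simulated counts and report expressed genes.

Computes both size-factor schemes (median-of-ratios and TMM), RPKM, the
expressed-gene report at 0.3 RPKM, the dispersion trend, and the VST.
Writes results/normalization/.
"""

from pathlib import Path

import pandas as pd

from ganglimark import diffexp, io, normalize

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cm, sd, ga, cfg = io.read_inputs(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "design.tsv",
        ROOT / "data" / "genes.tsv",
    )
    out = ROOT / "normalization"
    out.mkdir(parents=True, exist_ok=True)

    sf_mor = normalize.size_factors_median_of_ratios(cm)
    sf_tmm = normalize.tmm_factors(cm)
    io.write_table(
        pd.DataFrame({"median_of_ratios": sf_mor.factors, "tmm": sf_tmm.factors}),
        out / "size_factors.tsv", index_label="sample",
    )

    rpkm = normalize.rpkm_matrix(cm, ga.lengths_for(cm.gene_ids))
    per_sample, union = normalize.expressed_gene_report(
        rpkm, cfg.expressed_rpkm_threshold)
    io.write_table(per_sample.to_frame("n_expressed"),
                   out / "expressed_report.tsv", index_label="sample")

    disp = diffexp.fit_dispersion_model(cm, sf_mor.factors, sd)
    vst = normalize.vst_transform(cm, sf_mor, (disp.a0, disp.a1))
    io.write_table(vst, out / "vst.tsv", index_label="gene")
    io.write_table(
        pd.DataFrame({"mean": disp.mean, "raw_alpha": disp.raw_alpha,
                      "shrunken_alpha": disp.shrunken_alpha}, index=disp.gene_ids),
        out / "dispersions.tsv", index_label="gene",
    )

    print(f"size factors agree across schemes to "
          f"{(sf_mor.factors / sf_tmm.factors - 1).abs().max():.1%} (max)")
    print(f"{len(union)} of {cm.shape[0]} genes expressed above "
          f"{cfg.expressed_rpkm_threshold} RPKM in at least one sample "
          f"(per-sample range {per_sample.min()}-{per_sample.max()})")
    print(f"dispersion trend: alpha(mu) = {disp.a0:.4f} + {disp.a1:.3f}/mu")


if __name__ == "__main__":
    main()
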