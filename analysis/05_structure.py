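#!/usr/bin/env python
"""Sample structure: PCA, covariate screen, bootstrapped marker dendrogram.

PCA of the variance-stabilised expression should separate viscerosensory
(N, P) from somatosensory (Top, Tmm, VA) samples on PC1, no technical
covariate should correlate with any component, and average-linkage
clustering of marker expression should recover ((Top,Tmm),VA) | (N,P) with
high AU support.  Writes results/structure/.
"""

from pathlib import Path

from ganglimark import io, structure

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    _, sd, _, cfg = io.read_inputs(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "design.tsv",
        ROOT / "data" / "genes.tsv",
    )
    vst = io.read_table(ROOT / "normalization" / "vst.tsv")
    markers = io.read_table(ROOT / "markers" / "markers.tsv")
    out = ROOT / "structure"
    out.mkdir(parents=True, exist_ok=True)

    pca = structure.pca_samples(vst)
    io.write_table(pca.scores, out / "pca_scores.tsv", index_label="sample")
    screen = structure.pc_covariate_correlation(pca.scores, sd.covariates())
    io.write_table(screen, out / "pc_covariate_cor.tsv")

    root, support = structure.multiscale_bootstrap_support(
        vst.loc[markers.index], scales=cfg.bootstrap_scales,
        nboot=cfg.nboot, seed=cfg.seed,
    )
    io.write_table(support, out / "node_support.tsv")
    (out / "dendrogram.newick").write_text(root.newick() + ";\n")

    print(f"PC1/PC2 explain {pca.variance_explained[0]:.1%} / "
          f"{pca.variance_explained[1]:.1%} of variance")
    n_sig = int(screen["significant"].sum())
    print(f"covariate screen: {n_sig} significant (familywise) PC-covariate "
          f"pairs out of {int((~screen['undefined']).sum())} tested")
    big = support[support["members"].str.count(",") >= 5]
    print("support on multi-ganglion nodes:")
    print(big[["members", "au", "bp"]].to_string(index=False))


if __name__ == "__main__":
    main()
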