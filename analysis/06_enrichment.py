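#!/usr/bin/env python
"""Term over-representation of the marker panel.

EASE-adjusted hypergeometric tails against the expressed-gene background,
BH-corrected; the planted enriched terms should be flagged.  Writes
results/enrichment/.
"""

from pathlib import Path

from ganglimark import enrich, io, normalize

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cm, sd, ga, cfg = io.read_inputs(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "design.tsv",
        ROOT / "data" / "genes.tsv",
    )
    markers = io.read_table(ROOT / "markers" / "markers.tsv")
    rpkm = normalize.rpkm_matrix(cm, ga.lengths_for(cm.gene_ids))
    _, background = normalize.expressed_gene_report(
        rpkm, cfg.expressed_rpkm_threshold)
    table = enrich.enrich_terms(
        [g for g in markers.index if g in set(background)],
        background, ga.term_map(), cfg.enrichment_q_threshold,
    )
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(table.set_index("term"), out / "enrichment.tsv")

    planted = set((ROOT / "data" / "enriched_terms.txt").read_text().split())
    flagged = set(table[table["significant"]]["term"])
    print(table.head(6).to_string(index=False))
    print(f"{len(flagged)} significant terms; "
          f"{len(flagged & planted)}/{len(planted)} planted terms recovered")


if __name__ == "__main__":
    main()
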