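#!/usr/bin/env python
"""Consensus differential expression over every ganglion bipartition.

Runs both NB engines (conditional exact test; GLM-LRT) for all 30 high/low
partitions of the five ganglia and counts consensus calls per grouping.
Writes one DE table per grouping plus a summary under results/diffexp/.
"""

from pathlib import Path

import pandas as pd

from ganglimark import diffexp, io, normalize
from ganglimark.markers import enumerate_groupings

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cm, sd, ga, cfg = io.read_inputs(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "design.tsv",
        ROOT / "data" / "genes.tsv",
    )
    out = ROOT / "diffexp"
    out.mkdir(parents=True, exist_ok=True)
    sf_mor = normalize.size_factors_median_of_ratios(cm)
    sf_tmm = normalize.tmm_factors(cm)
    disp = diffexp.fit_dispersion_model(cm, sf_mor.factors, sd)

    counts = []
    for g in enumerate_groupings(sd.labels):
        de = diffexp.de_for_grouping(
            cm, sd, g.high, disp, sf_mor.factors, sf_tmm.factors,
            cfg.q_threshold,
        )
        name = g.id.replace("|", "_vs_").replace(",", "-")
        io.write_table(de, out / f"de_{name}.tsv", index_label="gene")
        counts.append({"grouping": g.id, "n_consensus_up": int(de["consensus"].sum())})
    summary = pd.DataFrame(counts).set_index("grouping").sort_values(
        "n_consensus_up", ascending=False)
    io.write_table(summary, out / "consensus_counts.tsv")
    print("consensus DE genes per grouping (top 8):")
    print(summary.head(8).to_string())
    nonzero = int((summary["n_consensus_up"] > 0).sum())
    print(f"{nonzero} of {len(summary)} groupings have at least one consensus gene")


if __name__ == "__main__":
    main()
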