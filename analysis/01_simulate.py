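#!/usr/bin/env python
"""Generate the default synthetic ganglion experiment.

Five cranial sensory ganglia (Top, Tmm, VA, P, N) x 3 replicates, 5000
genes at ~1.5 million counts per sample, with 101 planted markers
(|log2fc| >= 3) across eight groupings and 5 enriched annotation terms.
Writes counts/design/annotation plus the ground truth under results/data/.
"""

from pathlib import Path

import pandas as pd

from ganglimark import io
from ganglimark.simulate import SimulationConfig, simulate_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main():
    cfg = SimulationConfig(seed=SEED)
    cm, sd, ga, truth = simulate_experiment(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_table(cm.counts, OUT / "counts.tsv", index_label="gene")
    io.write_table(sd.table, OUT / "design.tsv", index_label="sample")
    io.write_table(ga.table, OUT / "genes.tsv", index_label="gene")
    rows = [{"gene": g, "grouping": grp, "log2fc": round(fc, 4)}
            for g, (grp, fc) in sorted(truth.marker_truth.items())]
    io.write_table(pd.DataFrame(rows).set_index("gene"), OUT / "truth.tsv")
    (OUT / "enriched_terms.txt").write_text(
        "\n".join(sorted(truth.enriched_terms)) + "\n")
    depth = cm.library_sizes()
    print(f"simulated {cm.shape[0]} genes x {cm.shape[1]} samples "
          f"(median depth {int(depth.median()):,} counts/sample)")
    print(f"planted {len(truth.marker_truth)} markers across "
          f"{len(set(g for g, _ in truth.marker_truth.values()))} groupings; "
          f"{len(truth.enriched_terms)} enriched terms")


if __name__ == "__main__":
    main()
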