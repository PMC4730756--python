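#!/usr/bin/env python
"""Apply the three-criterion marker filter and score against the truth.

A gene is a marker of a grouping when it is a consensus DE call, is
1.5-fold higher in every high-group sample than every low-group sample
(RPKM), and has RPKM >= 10 in every high-group sample.  Each marker is
assigned to its most specific passing grouping.  Writes results/markers/.
"""

from pathlib import Path

import pandas as pd

from ganglimark import io, normalize
from ganglimark.markers import select_markers, summarize_marker_counts

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cm, sd, ga, cfg = io.read_inputs(
        ROOT / "data" / "counts.tsv", ROOT / "data" / "design.tsv",
        ROOT / "data" / "genes.tsv",
    )
    de_by_grouping = {}
    for path in (ROOT / "diffexp").glob("de_*.tsv"):
        gid = path.stem[3:].replace("_vs_", "|").replace("-", ",")
        de_by_grouping[gid] = io.read_table(path)
    rpkm = normalize.rpkm_matrix(cm, ga.lengths_for(cm.gene_ids))
    markers = select_markers(de_by_grouping, rpkm, sd.table["ganglion"], cfg)
    summary = summarize_marker_counts(markers)

    out = ROOT / "markers"
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(markers, out / "markers.tsv", index_label="gene")
    io.write_table(summary, out / "marker_summary.tsv", index_label="grouping")

    truth = io.read_table(ROOT / "data" / "truth.tsv")
    reported, planted = set(markers.index), set(truth.index)
    sens = len(reported & planted) / len(planted)
    fdr = len(reported - planted) / max(len(reported), 1)
    print(summary.to_string())
    print(f"sensitivity vs planted truth: {sens:.3f}; empirical FDR: {fdr:.3f}")
    agree = sum(
        markers.at[g, "grouping"].split("|")[0] == truth.at[g, "grouping"]
        for g in reported & planted
    )
    print(f"{agree}/{len(reported & planted)} recovered markers assigned "
          f"to their planted grouping")


if __name__ == "__main__":
    main()
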