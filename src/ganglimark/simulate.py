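"""Synthetic NB count experiments with the study's group topology.

The generator emulates the structure of the real experiment — five cranial
sensory ganglia (trigeminal ophthalmic ``Top``, trigeminal maxillomandibular
``Tmm``, vestibulo-acoustic ``VA``, petrosal ``P``, nodose ``N``) with three
biological replicates each — so that every pipeline stage can be exercised
and scored against known truth without any external data.

Generative model per gene i and sample j of group g:

* baseline expression ``lambda_i`` is log-normal;
* group effects follow the known ganglion topology
  ``((Top,Tmm),VA) | (N,P)``: at each internal tree node an independent
  normal log2 shift splits the two sides, so groups within a clade
  co-vary — this reproduces the PCA geometry (viscerosensory vs
  somatosensory on PC1, then Top/Tmm vs VA);
* planted markers multiply the high-group mean by ``2**log2fc``
  (``log2fc >= planted_log2fc_min``) and carry no tree effect, so their
  expected fold change between any high and low group is the planted one;
* counts are NB with mean ``s_j * lambda_ij`` and dispersion
  ``alpha_i = a0 + a1 / lambda_i`` (variance ``mu + alpha*mu^2``);
* library-size factors ``s_j`` and gene lengths are log-normal; technical
  covariates (RIN, RNA yield) are generated independently of group so the
  covariate screen is null by construction.

Default sequencing depth is desk-scale (~1.5 million counts per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from ganglimark.containers import CountMatrix, GeneAnnotation, SampleDesign

GROUP_TREE = ((("Top", "Tmm"), ("VA",)), (("N",), ("P",)))

#: default number of planted markers per grouping id (high side only)
DEFAULT_PLANTING = {
    "N,P": 30,
    "Top,Tmm,VA": 20,
    "Top,Tmm": 9,
    "VA": 15,
    "N": 10,
    "P": 7,
    "Top": 5,
    "Tmm": 5,
}


@dataclass
class SimulationConfig:
    n_genes: int = 5000
    groups: tuple = ("Top", "Tmm", "VA", "P", "N")
    replicates_per_group: int = 3
    baseline_logmean_mu: float = float(np.log(100.0))
    baseline_logmean_sd: float = 1.5
    dispersion_a0: float = 0.01
    dispersion_a1: float = 2.0
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.25
    n_planted_per_grouping: dict = field(
        default_factory=lambda: dict(DEFAULT_PLANTING)
    )
    planted_log2fc_min: float = 3.0
    cluster_log2_spread: float = 0.2
    n_terms: int = 50
    genes_per_term: int = 40
    n_enriched_terms: int = 5
    gene_length_logmean: float = float(np.log(2500.0))
    gene_length_logsd: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion coefficients must be non-negative")
        if self.planted_log2fc_min < 0:
            raise ValueError("planted_log2fc_min must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with each simulated experiment."""

    marker_truth: dict          # gene_id -> (grouping high-side id, log2fc)
    enriched_terms: set
    group_tree: tuple = GROUP_TREE


def _tree_offsets(rng, n_genes: int, spread: float) -> dict[str, np.ndarray]:
    """Per-gene log2 group offsets from independent shifts at tree nodes.

    The shift scale halves at each level down the tree, so deep splits are
    subtler than the modality split — matching the observed hierarchy
    strength (the somato/viscero split dominates PC1).
    """
    d_root = rng.normal(0.0, spread, n_genes)
    d_soma = rng.normal(0.0, spread / 2, n_genes)   # (Top,Tmm) vs VA
    d_tt = rng.normal(0.0, spread / 4, n_genes)     # Top vs Tmm
    d_np = rng.normal(0.0, spread / 2, n_genes)     # N vs P
    return {
        "Top": +d_root / 2 + d_soma / 2 + d_tt / 2,
        "Tmm": +d_root / 2 + d_soma / 2 - d_tt / 2,
        "VA": +d_root / 2 - d_soma / 2,
        "N": -d_root / 2 + d_np / 2,
        "P": -d_root / 2 - d_np / 2,
    }


#: baseline floor (expected counts per unit size factor) for planting
#: markers — keeps planted genes in the robustly quantified range, as real
#: markers must be to clear the RPKM >= 10 criterion
PLANT_BASELINE_MIN = 50.0


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, SampleDesign, GeneAnnotation, SyntheticTruth]:
    """Draw one synthetic experiment; fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.groups)
    reps = cfg.replicates_per_group
    n_samples = len(groups) * reps
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"{g}_{r + 1}" for g in groups for r in range(reps)]
    sample_group = np.repeat(groups, reps)

    lam = rng.lognormal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sd, cfg.n_genes)
    lengths = np.maximum(
        rng.lognormal(cfg.gene_length_logmean, cfg.gene_length_logsd, cfg.n_genes),
        200.0,
    ).astype(int)
    s = rng.lognormal(cfg.libsize_logmean, cfg.libsize_logsd, n_samples)

    offsets = _tree_offsets(rng, cfg.n_genes, cfg.cluster_log2_spread)

    n_wanted = sum(cfg.n_planted_per_grouping.values())
    if n_wanted > cfg.n_genes:
        raise ValueError(
            f"{n_wanted} planted genes requested but only {cfg.n_genes} genes"
        )
    eligible = np.flatnonzero(lam >= PLANT_BASELINE_MIN)
    if n_wanted > eligible.size:
        raise ValueError(
            f"{n_wanted} planted genes requested but only {eligible.size} "
            f"genes have baseline >= {PLANT_BASELINE_MIN}"
        )
    chosen = rng.choice(eligible, size=n_wanted, replace=False) if n_wanted else []
    marker_truth: dict[str, tuple[str, float]] = {}
    planted_fc = np.zeros((cfg.n_genes, len(groups)))
    pos = 0
    for gid_high, count in cfg.n_planted_per_grouping.items():
        high = set(gid_high.split(","))
        unknown = high - set(groups)
        if unknown:
            raise ValueError(f"unknown group(s) in planting map: {sorted(unknown)}")
        for _ in range(count):
            i = int(chosen[pos]); pos += 1
            fc = cfg.planted_log2fc_min + rng.uniform(0.0, 0.5)
            for gi, g in enumerate(groups):
                if g in high:
                    planted_fc[i, gi] = fc
            for g in offsets:  # planted genes carry no tree effect
                offsets[g][i] = 0.0
            marker_truth[gene_ids[i]] = (",".join(sorted(high)), float(fc))

    log2_mu = np.log2(lam)[:, None] + np.stack(
        [offsets[g] for g in groups], axis=1
    ) + planted_fc
    group_mean = 2.0 ** log2_mu                       # genes x groups
    mean_mat = group_mean[:, [groups.index(g) for g in sample_group]] * s[None, :]

    alpha = cfg.dispersion_a0 + cfg.dispersion_a1 / lam
    counts = np.empty((cfg.n_genes, n_samples), dtype=np.int64)
    for gi in range(len(groups)):
        cols = np.flatnonzero(sample_group == groups[gi])
        for j in cols:
            m = mean_mat[:, j]
            if np.all(alpha <= 0):
                counts[:, j] = rng.poisson(m)
            else:
                r = 1.0 / np.maximum(alpha, 1e-12)
                counts[:, j] = rng.negative_binomial(r, r / (r + m))

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))

    design = pd.DataFrame(
        {
            "ganglion": sample_group,
            "replicate": [r + 1 for _ in groups for r in range(reps)],
            "rin": np.round(rng.normal(8.5, 0.6, n_samples), 2),
            "rna_yield_ng": np.round(rng.lognormal(np.log(120.0), 0.4, n_samples), 1),
            # nominal sequencing depth: driven by the library-size factor
            # (itself group-independent), not by the realised counts — a
            # group's marker content must not leak into a technical covariate
            "read_depth": (s * 1.5e6 * rng.lognormal(0.0, 0.05, n_samples)).astype(int),
        },
        index=sample_ids,
    )
    sd = SampleDesign(design)

    # term annotation: random term-gene sets, some seeded with markers
    term_rows = {g: set() for g in gene_ids}
    enriched = set()
    marker_list = list(marker_truth)
    for t in range(cfg.n_terms):
        term = f"T{t + 1:04d}"
        if t < cfg.n_enriched_terms and marker_list:
            n_from_markers = min(cfg.genes_per_term // 2, len(marker_list))
            hit = rng.choice(marker_list, size=n_from_markers, replace=False)
            rest = rng.choice(
                cfg.n_genes, size=cfg.genes_per_term - n_from_markers, replace=False
            )
            members = set(hit) | {gene_ids[i] for i in rest}
            enriched.add(term)
        else:
            members = {
                gene_ids[i]
                for i in rng.choice(cfg.n_genes, size=cfg.genes_per_term, replace=False)
            }
        for g in members:
            term_rows[g].add(term)
    annot = pd.DataFrame(
        {
            "length_bp": lengths,
            "terms": [";".join(sorted(term_rows[g])) for g in gene_ids],
        },
        index=gene_ids,
    )
    ga = GeneAnnotation(annot)
    truth = SyntheticTruth(marker_truth, enriched)
    return cm, sd, ga, truth


def null_simulation_config(seed: int = 0, n_genes: int = 2000) -> SimulationConfig:
    """A no-effect configuration: no tree structure, no planted markers.

    Used for type-I-error calibration of the DE engines and the covariate
    screen.
    """
    return SimulationConfig(
        n_genes=n_genes,
        cluster_log2_spread=0.0,
        n_planted_per_grouping={},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic toy fixture (literal table, used by unit tests and docs)

_TOY_TSV = (
    "gene	Top_1	Top_2	Top_3	Tmm_1	Tmm_2	Tmm_3	VA_1	VA_2	VA_3	P_1	P_2	P_3	N_1	N_2	N_3\n"
    "M_NP_1	6	7	8	9	10	6	7	8	9	915	937	959	900	922	944\n"
    "M_NP_2	9	10	6	7	8	9	10	6	7	930	952	914	915	937	959\n"
    "M_SOM_1	930	952	914	915	937	959	900	922	944	6	7	8	9	10	6\n"
    "M_SOM_2	945	907	929	930	952	914	915	937	959	9	10	6	7	8	9\n"
    "M_TRI_1	900	922	944	945	907	929	9	10	6	7	8	9	10	6	7\n"
    "M_TRI_2	915	937	959	900	922	944	7	8	9	10	6	7	8	9	10\n"
    "M_VA_1	9	10	6	7	8	9	900	922	944	8	9	10	6	7	8\n"
    "M_VA_2	7	8	9	10	6	7	915	937	959	6	7	8	9	10	6\n"
    "BG_01	149	111	136	104	129	154	122	147	109	140	102	127	158	120	145\n"
    "BG_02	127	158	120	145	113	138	100	131	156	118	149	111	136	104	129\n"
    "BG_03	111	136	104	129	154	122	147	109	140	102	127	158	120	145	113\n"
    "BG_04	158	120	145	113	138	100	131	156	118	149	111	136	104	129	154\n"
    "BG_05	136	104	129	154	122	147	109	140	102	127	158	120	145	113	138\n"
    "BG_06	120	145	113	138	100	131	156	118	149	111	136	104	129	154	122\n"
    "BG_07	104	129	154	122	147	109	140	102	127	158	120	145	113	138	100\n"
    "BG_08	145	113	138	100	131	156	118	149	111	136	104	129	154	122	147\n"
    "BG_09	129	154	122	147	109	140	102	127	158	120	145	113	138	100	131\n"
    "BG_10	113	138	100	131	156	118	149	111	136	104	129	154	122	147	109\n"
    "BG_11	154	122	147	109	140	102	127	158	120	145	113	138	100	131	156\n"
    "BG_12	138	100	131	156	118	149	111	136	104	129	154	122	147	109	140\n"
    ""
)

_TOY_DESIGN_TSV = (
    "sample	ganglion	replicate	rin	rna_yield_ng	read_depth\n"
    "Top_1	Top	1	8.1	110	5305\n"
    "Top_2	Top	2	8.4	95	5283\n"
    "Top_3	Top	3	8.9	130	5314\n"
    "Tmm_1	Tmm	1	8.6	120	5271\n"
    "Tmm_2	Tmm	2	8.2	105	5307\n"
    "Tmm_3	Tmm	3	8.8	140	5343\n"
    "VA_1	VA	1	8.3	98	5175\n"
    "VA_2	VA	2	9.0	125	5334\n"
    "VA_3	VA	3	8.5	115	5367\n"
    "P_1	P	1	8.7	132	3430\n"
    "P_2	P	2	8.0	102	3484\n"
    "P_3	P	3	8.6	118	3478\n"
    "N_1	N	1	8.9	127	3430\n"
    "N_2	N	2	8.2	99	3421\n"
    "N_3	N	3	8.4	121	3533\n"
    ""
)

_TOY_GENES_TSV = (
    "gene	length_bp	terms\n"
    "M_NP_1	800	T_VISC;T_MISC\n"
    "M_NP_2	937	T_VISC\n"
    "M_SOM_1	1074	T_VISC;T_SOMA\n"
    "M_SOM_2	1211	T_SOMA;T_MISC\n"
    "M_TRI_1	1348	T_SOMA\n"
    "M_TRI_2	1485	T_SOMA\n"
    "M_VA_1	1622	T_SOMA;T_MISC\n"
    "M_VA_2	1759	T_SOMA\n"
    "BG_01	1896	\n"
    "BG_02	800	T_MISC\n"
    "BG_03	937	\n"
    "BG_04	1074	\n"
    "BG_05	1211	T_MISC\n"
    "BG_06	1348	\n"
    "BG_07	1485	\n"
    "BG_08	1622	T_MISC\n"
    "BG_09	1759	\n"
    "BG_10	1896	\n"
    "BG_11	800	T_MISC\n"
    "BG_12	937	\n"
    ""
)

#: groupings (high side) of the eight planted toy markers, two per grouping
TOY_MARKERS = {
    "M_NP_1": "N,P",
    "M_NP_2": "N,P",
    "M_SOM_1": "Top,Tmm,VA",
    "M_SOM_2": "Top,Tmm,VA",
    "M_TRI_1": "Top,Tmm",
    "M_TRI_2": "Top,Tmm",
    "M_VA_1": "VA",
    "M_VA_2": "VA",
}


def toy_fixture() -> tuple[CountMatrix, SampleDesign, GeneAnnotation]:
    """A fixed 20-gene x 15-sample dataset with two markers per grouping.

    The table is a literal constant (byte-identical across calls): eight
    planted markers — two each for N/P, Top/Tmm/VA, Top/Tmm and VA — with
    clean high/low separation, over twelve flat background genes.
    """
    cm = CountMatrix(pd.read_csv(StringIO(_TOY_TSV), sep="\t", index_col=0))
    sd = SampleDesign(pd.read_csv(StringIO(_TOY_DESIGN_TSV), sep="\t", index_col=0))
    ga = GeneAnnotation(pd.read_csv(StringIO(_TOY_GENES_TSV), sep="\t", index_col=0))
    return cm, sd, ga
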