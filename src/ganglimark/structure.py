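"""Sample-structure analyses: PCA, covariate screens, and bootstrapped trees.

PCA is run on variance-stabilised expression (samples as observations,
genes centred, no scaling) and the leading components are screened for
correlation with technical covariates (RIN, RNA yield, read depth) — in the
study none correlated, supporting a biological interpretation of the
clusters.

The marker dendrogram clusters samples by 1 - Pearson correlation with
average linkage, and every internal node carries multiscale-bootstrap
support: genes are resampled at several scales r (resample round(n*r) genes
with replacement), the per-scale recovery frequency of the node's exact
member set is recorded, and the two-parameter model

    Phi^-1(1 - BP_r) = v*sqrt(r) + c/sqrt(r)

is fitted by weighted least squares.  The approximately unbiased p-value is
AU = 1 - Phi(v - c) and the (fitted) bootstrap probability is
BP = 1 - Phi(v + c); AU corrects the scale-dependent bias of the plain
bootstrap proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr


# ---------------------------------------------------------------------------
# PCA and covariate screen


@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # genes x components
    variance_explained: np.ndarray

    def __post_init__(self):
        ve = self.variance_explained
        if np.any(np.diff(ve) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")


def pca_samples(vst: pd.DataFrame) -> PCAResult:
    """PCA of samples over gene features via SVD of the centred matrix.

    ``vst`` is genes x samples; each gene is centred across samples and no
    scaling is applied.  Sign convention: the largest-magnitude loading of
    each component is made positive (deterministic orientation).
    """
    if vst.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    X = vst.to_numpy(dtype=float).T          # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("constant matrix: no variance to decompose")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # orient: largest-|loading| positive per component
    for k in range(S.size):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    comp = [f"PC{i + 1}" for i in range(S.size)]
    scores = pd.DataFrame(U * S, index=vst.columns, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=vst.index, columns=comp)
    ve = S ** 2 / np.sum(S ** 2)
    return PCAResult(scores, loadings, ve)


def pc_covariate_correlation(
    scores: pd.DataFrame, covariates: pd.DataFrame, fw_alpha: float = 0.01
) -> pd.DataFrame:
    """Pearson correlation of each component with each technical covariate.

    p-values come from the exact two-sided t reference
    ``t = r * sqrt((n-2) / (1-r^2))``.  Constant covariates (or components
    with zero score variance) are flagged undefined rather than given a
    numeric correlation.

    The screen's claim is familywise ("no component correlates with any
    covariate"), so the ``significant`` flag applies a Bonferroni-adjusted
    threshold over the tested pairs: ``p_adj = p * m`` and significance at
    ``p_adj < fw_alpha``.
    """
    rows = []
    # components whose score variance is numerically zero (singular values
    # at machine precision, e.g. the trailing PC of a centred matrix) carry
    # no usable signal and are reported undefined
    score_scale = float(np.std(scores.to_numpy(dtype=float)))
    for comp in scores.columns:
        x = scores[comp].to_numpy(dtype=float)
        for cov in covariates.columns:
            y = covariates.loc[scores.index, cov].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) <= 1e-9 * score_scale:
                rows.append((comp, cov, np.nan, np.nan, True))
                continue
            r, p = pearsonr(x, y)
            rows.append((comp, cov, float(r), float(p), False))
    out = pd.DataFrame(
        rows, columns=["component", "covariate", "r", "p", "undefined"]
    )
    m = int((~out["undefined"]).sum())
    out["p_adj"] = np.minimum(out["p"] * max(m, 1), 1.0)
    out["significant"] = out["p_adj"] < fw_alpha
    return out


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class DendrogramNode:
    """A cluster of leaves with height and (optionally) bootstrap support."""

    members: frozenset
    height: float = 0.0
    children: tuple | None = None
    au: float | None = None
    bp: float | None = None
    v: float | None = None
    c: float | None = None
    flags: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def internal_nodes(self):
        """Yield all internal nodes, this one included, children first."""
        if self.is_leaf:
            return
        for ch in self.children:
            yield from ch.internal_nodes()
        yield self

    def newick(self, parent_height: float | None = None) -> str:
        """Newick string; internal nodes labelled with AU (when present)."""
        if self.is_leaf:
            name = next(iter(self.members))
            s = str(name)
        else:
            s = "(" + ",".join(
                ch.newick(self.height) for ch in
                sorted(self.children, key=lambda n: sorted(n.members))
            ) + ")"
            if self.au is not None:
                s += f"{self.au:.3f}"
        if parent_height is not None:
            s += f":{max(parent_height - self.height, 0.0):.6g}"
        return s


def correlation_distances(matrix: pd.DataFrame, strict: bool = True) -> np.ndarray:
    """1 - Pearson distance between columns of a genes x items matrix.

    With ``strict`` a zero-variance column raises (correlation undefined);
    otherwise such columns get distance 1 to everything (bootstrap path).
    """
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if strict and (sd == 0).any():
        bad = matrix.columns[int(np.argmin(sd))]
        raise ValueError(f"zero-variance item {bad!r}: correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.T)
    D = 1.0 - corr
    D[~np.isfinite(D)] = 1.0
    np.fill_diagonal(D, 0.0)
    return D


def hierarchical_cluster(matrix: pd.DataFrame, strict: bool = True) -> DendrogramNode:
    """Average-linkage agglomeration of columns under 1 - Pearson distance.

    Ties on merge distance are broken by the lexicographically smallest
    pair of cluster keys (a cluster's key is its sorted member tuple), which
    makes the tree fully deterministic.
    """
    items = list(matrix.columns)
    if len(items) < 2:
        raise ValueError("need at least 2 items to cluster")
    D = correlation_distances(matrix, strict=strict)
    nodes = {i: DendrogramNode(frozenset([items[i]])) for i in range(len(items))}
    sizes = {i: 1 for i in nodes}
    keys = {i: (items[i],) for i in nodes}
    dist = {}
    active = sorted(nodes)
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            dist[(a, b)] = D[a, b]
    nxt = len(items)
    while len(active) > 1:
        best = None
        for ia, a in enumerate(active):
            for b in active[ia + 1:]:
                d = dist[(min(a, b), max(a, b))]
                pair_key = tuple(sorted((keys[a], keys[b])))
                cand = (d, pair_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, _, a, b = best
        merged = DendrogramNode(
            nodes[a].members | nodes[b].members,
            height=float(d),
            children=(nodes[a], nodes[b]),
        )
        nodes[nxt] = merged
        sizes[nxt] = sizes[a] + sizes[b]
        keys[nxt] = tuple(sorted(merged.members))
        for k in active:
            if k in (a, b):
                continue
            da = dist[(min(a, k), max(a, k))]
            db = dist[(min(b, k), max(b, k))]
            dist[(min(nxt, k), max(nxt, k))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        active = [k for k in active if k not in (a, b)] + [nxt]
        nxt += 1
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# multiscale bootstrap support


def _node_member_sets(root: DendrogramNode) -> list[frozenset]:
    return [n.members for n in root.internal_nodes()]


def multiscale_bootstrap_support(
    matrix: pd.DataFrame,
    scales=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4),
    nboot: int = 1000,
    seed: int = 0,
) -> tuple[DendrogramNode, pd.DataFrame]:
    """Cluster columns and attach AU/BP support to every internal node.

    For each scale ``r``, ``nboot`` resamples of ``round(n_genes * r)`` gene
    rows (with replacement) are reclustered and the recovery frequency of
    each original node's exact member set recorded.  Frequencies are clamped
    to ``[1/(2*nboot), 1 - 1/(2*nboot)]`` before probit transformation, and
    the signed-distance / curvature model is fitted by weighted least
    squares.  Returns the annotated tree and a per-node support table.
    """
    scales = [float(r) for r in scales]
    if not any(abs(r - 1.0) < 1e-9 for r in scales):
        raise ValueError("scales must include 1.0")
    if nboot < 10:
        raise ValueError("nboot must be at least 10")
    rng = np.random.default_rng(seed)
    root = hierarchical_cluster(matrix)
    targets = _node_member_sets(root)
    n_genes = matrix.shape[0]
    counts = {m: np.zeros(len(scales)) for m in targets}
    X = matrix
    for si, r in enumerate(scales):
        nr = max(int(round(n_genes * r)), 2)
        for _ in range(nboot):
            idx = rng.integers(0, n_genes, size=nr)
            boot = X.iloc[idx]
            rt = hierarchical_cluster(boot, strict=False)
            found = set(_node_member_sets(rt))
            for m in targets:
                if m in found:
                    counts[m][si] += 1

    lo, hi = 1.0 / (2 * nboot), 1.0 - 1.0 / (2 * nboot)
    sq = np.sqrt(np.asarray(scales))
    rows = []
    for node in root.internal_nodes():
        m = node.members
        bp_raw = counts[m] / nboot
        flags = []
        if np.all(bp_raw == 0):
            node.au, node.bp, node.v, node.c = 0.0, 0.0, np.nan, np.nan
            flags.append("never_recovered")
        else:
            clamped = np.clip(bp_raw, lo, hi)
            is_clamped = (bp_raw < lo) | (bp_raw > hi)
            if int(is_clamped.sum()) >= len(scales) / 2:
                flags.append("clamped")
            z = norm.ppf(1.0 - clamped)
            w = nboot * norm.pdf(z) ** 2 / (clamped * (1.0 - clamped))
            informative = ~is_clamped
            # A flat probit profile carries no scale information: the
            # two-term model is then unidentifiable (a constant is not in
            # the span of sqrt(r), 1/sqrt(r)) and a naive fit would distort
            # AU badly.  Such profiles reduce to v = mean probit, c = 0 —
            # so a node recovered at a constant rate b gets AU = BP = b.
            if np.ptp(z) < 1e-12 or informative.sum() < 2:
                v = float(np.sum(w * z) / np.sum(w))
                c = 0.0
                flags.append("degenerate_profile")
            else:
                zi, wi, sqi = z[informative], w[informative], sq[informative]
                A = np.column_stack([sqi, 1.0 / sqi])
                WA = A * wi[:, None]
                coef = np.linalg.solve(A.T @ WA, WA.T @ zi)
                v, c = float(coef[0]), float(coef[1])
            node.v, node.c = v, c
            node.au = float(1.0 - norm.cdf(v - c))
            node.bp = float(1.0 - norm.cdf(v + c))
        node.flags = flags
        idx1 = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
        rows.append(
            {
                "members": ",".join(sorted(str(x) for x in m)),
                "au": node.au,
                "bp": node.bp,
                "v": node.v,
                "c": node.c,
                "bp_raw_scale1": bp_raw[idx1],
                "flags": ";".join(flags),
            }
        )
    table = pd.DataFrame(rows)
    return root, table
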