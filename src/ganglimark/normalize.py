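"""Between-sample normalisation and expression transforms.

Two size-factor schemes are provided, mirroring the two normalisations the
study applied to the same count matrix:

* **median-of-ratios** — each sample's factor is the median, over genes
  positive in every sample, of the ratio of the sample's count to the gene's
  geometric mean across samples.
* **TMM** (trimmed mean of M-values) — each sample's factor is
  ``2**(weighted trimmed mean of per-gene log2 ratios vs a reference)``,
  with the standard 30 % trim on M, 5 % trim on A and inverse
  asymptotic-variance weights; factors are rescaled to geometric mean 1.

Also here: RPKM (reads per kilobase per million), the expressed-gene report
at the study's 0.3 RPKM threshold, and a closed-form variance-stabilising
transform (VST) for negative-binomial counts whose dispersion follows the
parametric trend alpha(mu) = a0 + a1/mu.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ganglimark.containers import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizationFactors:
    """Per-sample size factors under a named scheme."""

    factors: pd.Series
    scheme: str

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("size factors must all be positive")
        if self.scheme not in ("median_of_ratios", "tmm"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def size_factors_median_of_ratios(cm: CountMatrix) -> NormalizationFactors:
    """Median-of-ratios size factors.

    For each gene positive in every sample, form the ratio of each sample's
    count to the gene's geometric mean across samples; the sample's factor
    is the median of its ratios.

    Raises
    ------
    ValueError
        If no gene is positive in all samples (factors undefined); filter
        to better-covered genes first.
    """
    arr = cm.values.astype(float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "median-of-ratios undefined: no gene has positive counts in every "
            "sample; filter the matrix to genes detected in all samples"
        )
    sub = arr[allpos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo)
    s = np.median(ratios, axis=0)
    return NormalizationFactors(
        pd.Series(s, index=cm.sample_ids), "median_of_ratios"
    )


def _tmm_pair_factor(
    y: np.ndarray,
    yr: np.ndarray,
    lib: float,
    libr: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (y > 0) & (yr > 0)
    y, yr = y[keep].astype(float), yr[keep].astype(float)
    if y.size == 0:
        raise ValueError("no gene is positive in both sample and reference")
    # M on raw counts: the factor absorbs depth as well as composition, so
    # it is directly comparable to a median-of-ratios size factor
    m = np.log2(y / yr)
    a = 0.5 * np.log2((y / lib) * (yr / libr))
    # asymptotic variance of M per gene (delta method on binomial counts)
    w = (lib - y) / (lib * y) + (libr - yr) / (libr * yr)
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        keep2 = np.ones(n, bool)
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(
    cm: CountMatrix,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values size factors.

    With ``reference=None`` the reference sample is the one whose
    upper-quartile of library-scaled counts is closest to the mean
    upper-quartile.  The returned factors are rescaled to geometric mean 1,
    so they are comparable across runs and to median-of-ratios output.
    """
    arr = cm.values
    libs = arr.sum(axis=0).astype(float)
    if (libs == 0).any():
        dead = cm.sample_ids[int(np.argmin(libs))]
        raise ValueError(f"sample {dead!r} has zero total counts")
    uq = np.array([np.quantile(arr[:, j] / libs[j], 0.75) for j in range(arr.shape[1])])
    if reference is None:
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = cm.sample_ids.index(reference)
    logf = np.zeros(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref_idx:
            continue
        logf[j] = _tmm_pair_factor(
            arr[:, j], arr[:, ref_idx], libs[j], libs[ref_idx], trim_m, trim_a
        )
    logf -= logf.mean()  # geometric mean 1
    return NormalizationFactors(
        pd.Series(2.0 ** logf, index=cm.sample_ids), "tmm"
    )


def rpkm_matrix(
    cm: CountMatrix,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of gene model per million mapped reads.

    ``rpkm = count * 1e9 / (length_bp * library_size)``; the library size
    defaults to the raw column sum of the count matrix.
    """
    lengths = gene_lengths.loc[cm.gene_ids].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = cm.library_sizes()
    libs = library_sizes.loc[cm.sample_ids].astype(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    vals = cm.values * 1e9 / np.outer(lengths.to_numpy(), libs.to_numpy())
    return pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids)


def expressed_gene_report(
    rpkm: pd.DataFrame, threshold: float = 0.3
) -> tuple[pd.Series, list[str]]:
    """Per-sample expressed-gene counts and the union expressed set.

    A gene counts as expressed in a sample iff its RPKM is strictly above
    ``threshold`` (the study's ``> 0.3`` criterion).  The union over samples
    is the background used for term enrichment.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mask = rpkm > threshold
    per_sample = mask.sum(axis=0)
    union = list(rpkm.index[mask.any(axis=1)])
    return per_sample, union


def vst_transform(
    cm: CountMatrix,
    size_factors: NormalizationFactors | pd.Series,
    dispersion_trend: tuple[float, float],
) -> pd.DataFrame:
    """Closed-form variance-stabilising transform.

    For NB counts with dispersion trend ``alpha(mu) = a0 + a1/mu`` the
    variance of a count with mean ``mu`` is ``mu*(1+a1) + a0*mu**2``; the
    integral of ``1/sqrt(var)`` has the closed form used here.  With
    ``q = count / size_factor``::

        vst(q) = log2( (1 + a1 + 2*a0*q + 2*sqrt(a0*q*(1 + a1 + a0*q)))
                       / (4*a0) )

    which is strictly increasing in ``q`` and asymptotically log2.  If
    ``a0 <= 0`` (no shot-noise-free quadratic term was fitted) the transform
    falls back to ``log2(q + 0.5)`` and logs the fallback.
    """
    s = size_factors.factors if isinstance(size_factors, NormalizationFactors) else size_factors
    s = s.loc[cm.sample_ids].astype(float)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    a0, a1 = dispersion_trend
    q = cm.values / s.to_numpy()[None, :]
    if a0 <= 0:
        logger.info("vst: a0 <= 0, falling back to log2(q + 0.5)")
        vals = np.log2(q + 0.5)
    else:
        vals = np.log2(
            (1 + a1 + 2 * a0 * q + 2 * np.sqrt(a0 * q * (1 + a1 + a0 * q)))
            / (4 * a0)
        )
    return pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids)
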