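"""Low-count filtering, TMM normalization and log2-CPM transformation.

The functions here reproduce the default count-preprocessing conventions of
the edgeR bulk RNA-seq workflow: genes with very low counts across all
samples are dropped, per-sample composition-correction factors are estimated
by the trimmed mean of M-values (TMM), and counts are put on a
log2 counts-per-million scale using the resulting *effective* library sizes
(raw depth x TMM factor) with a depth-scaled prior count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "NormalizationResult",
    "validate_counts",
    "filter_low_counts",
    "tmm_factors",
    "log_cpm",
]


@dataclass(frozen=True)
class NormalizationResult:
    """Per-sample library sizes, TMM factors and effective library sizes.

    ``effective_sizes = library_sizes * tmm_factors``; the factors are
    rescaled so that their geometric mean is 1, which keeps the average
    effective depth on the scale of the raw depths.
    """

    library_sizes: pd.Series
    tmm_factors: pd.Series
    effective_sizes: pd.Series

    def __post_init__(self) -> None:
        log_gm = float(np.mean(np.log(self.tmm_factors.to_numpy(float))))
        if abs(log_gm) > 1e-9:
            raise ValueError("tmm_factors must have geometric mean 1")
        if not (self.effective_sizes.to_numpy(float) > 0).all():
            raise ValueError("effective_sizes must be strictly positive")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples count matrix and return it unchanged.

    Raises ``ValueError`` on negative entries, duplicate gene or sample
    identifiers, non-integral values, or fewer than 2 samples.
    """
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    if counts.shape[1] < 2:
        raise ValueError("count matrix needs at least 2 samples")
    x = counts.to_numpy()
    if not np.issubdtype(x.dtype, np.number):
        raise ValueError("counts must be numeric")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(x, np.round(x)):
        raise ValueError("counts must be integer-valued")
    return counts


def filter_low_counts(
    counts: pd.DataFrame,
    groups: Sequence,
    min_count: int = 10,
    min_total: int = 15,
) -> pd.DataFrame:
    """Remove genes with very low counts across all samples.

    A gene is kept when its CPM exceeds the cutoff implied by ``min_count``
    at the median library size in at least ``k`` samples, where ``k`` is the
    size of the smallest group, and its total count is at least
    ``min_total``. Row order of the survivors is preserved.
    """
    validate_counts(counts)
    groups = np.asarray(groups)
    if groups.shape[0] != counts.shape[1]:
        raise ValueError("groups must have one label per sample")
    lib = counts.sum(axis=0).to_numpy(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive total count")
    k = int(pd.Series(groups).value_counts().min())
    cutoff = min_count / np.median(lib) * 1e6
    cpm = counts.to_numpy(float) / lib * 1e6
    # tiny tolerance so genes sitting exactly on the cutoff are kept
    keep = ((cpm >= cutoff - 1e-10).sum(axis=1) >= k) & (
        counts.sum(axis=1).to_numpy(float) >= min_total - 1e-10
    )
    if not keep.any():
        raise ValueError("all genes removed by the low-count filter")
    return counts.loc[keep]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one column against the reference column (log2 scale -> 2**f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / n_obs / obs + (n_ref - ref) / n_ref / ref
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationResult:
    """Trimmed-mean-of-M-values composition factors for every sample.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction. For every other sample the
    factor is 2**(weighted trimmed mean of gene-wise log2 CPM ratios M),
    with genes zero in either column dropped, double trimming by M
    (``trim_m``, each tail) and by average abundance A (``trim_a``), and
    precision weights from the asymptotic (delta-method) variance of M.
    Factors are rescaled to geometric mean 1.
    """
    validate_counts(counts)
    x = counts.to_numpy(float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        j = int(np.where(lib <= 0)[0][0])
        raise ValueError(f"sample {counts.columns[j]!r} has zero total count")
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    lib_s = pd.Series(lib.astype(np.int64), index=counts.columns, name="library_size")
    fac_s = pd.Series(factors, index=counts.columns, name="tmm_factor")
    return NormalizationResult(
        library_sizes=lib_s,
        tmm_factors=fac_s,
        effective_sizes=(lib_s * fac_s).rename("effective_size"),
    )


def log_cpm(
    counts: pd.DataFrame,
    norm: NormalizationResult | None = None,
    prior_count: float = 2.0,
) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes.

    The prior count is scaled per sample in proportion to effective depth,
    so a gene with equal counts in equal-depth samples gets equal values:

        value = log2((count + prior_s) / (size_s + 2 * prior_s) * 1e6)

    with ``prior_s = prior_count * size_s / mean(size)``.
    """
    validate_counts(counts)
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    if norm is None:
        norm = tmm_factors(counts)
    if list(norm.effective_sizes.index) != list(counts.columns):
        raise ValueError("normalization result does not match the count matrix samples")
    size = norm.effective_sizes.to_numpy(float)
    prior = prior_count * size / size.mean()
    vals = np.log2((counts.to_numpy(float) + prior) / (size + 2.0 * prior) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)
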