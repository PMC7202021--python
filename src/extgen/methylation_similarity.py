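"""Accession-level windowed CG methylation and the similarity matrix M.

Replicate call sets are pooled per accession (read counts added per site),
CG sites are binned into non-overlapping 200 bp windows on a genome-anchored
grid, and each window's methylation level is the pooled-count ratio
sum(meth)/sum(total) — not a mean of per-site ratios.  Windows with fewer
than 10 reads in an accession are missing for that accession; windows missing
in more than half the accessions, or carrying no methylated read at all, are
dropped.  Columns of the remaining proportion matrix Q are standardized
(population variance over the observed entries), missing cells contribute 0
to the cross-product, and

    M = Q Q' / N        (elementwise)

where N_ij counts windows observed in both accessions i and j.  This is a
pairwise-complete correlation-like similarity; it can be slightly non-PSD
and is eigenvalue-bent before use as a covariance structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CytosineCallSet
from .relatedness import CovarianceStructure

logger = logging.getLogger(__name__)

__all__ = [
    "WindowMethylationMatrix",
    "SimilarityStructure",
    "pool_replicates",
    "window_proportions",
    "filter_windows",
    "similarity_matrix",
]


@dataclass
class WindowMethylationMatrix:
    """Accession x window methylation proportions with coverage and counts.

    All three frames share the same index (accessions) and columns
    (``"chrom:start"`` window keys, 0-based half-open starts).  A proportion
    is present exactly where the window's pooled coverage meets the read
    threshold used to build it.
    """

    proportions: pd.DataFrame
    coverage: pd.DataFrame
    meth_counts: pd.DataFrame
    window_size: int = 200
    min_reads: int = 10

    def __post_init__(self) -> None:
        for name in ("coverage", "meth_counts"):
            f = getattr(self, name)
            if not (f.index.equals(self.proportions.index) and f.columns.equals(self.proportions.columns)):
                raise ValueError(f"{name} frame is not aligned with proportions")

    @property
    def accession_labels(self) -> list[str]:
        return [str(x) for x in self.proportions.index]

    @property
    def n_windows(self) -> int:
        return self.proportions.shape[1]

    @property
    def missing_fraction(self) -> pd.Series:
        return self.proportions.isna().mean(axis=0)


@dataclass
class SimilarityStructure:
    """Methylation similarity M with its pairwise-observation count matrix N."""

    m: np.ndarray
    n_shared: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.n_shared = np.asarray(self.n_shared, dtype=int)
        k = len(self.labels)
        if self.m.shape != (k, k) or self.n_shared.shape != (k, k):
            raise ValueError("similarity matrices do not match label count")

    def to_covariance(self, bend: bool = True) -> CovarianceStructure:
        cov = CovarianceStructure(values=self.m, labels=self.labels, kind="methylation")
        return cov.bend() if bend else cov

    def m_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.m, index=self.labels, columns=self.labels)

    def n_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.n_shared, index=self.labels, columns=self.labels)


def pool_replicates(
    calls: list[CytosineCallSet],
    accession_map: dict[str, str],
) -> dict[str, CytosineCallSet]:
    """Sum replicate read counts per accession, site by site.

    Sites absent from a replicate simply contribute nothing.  Every accession
    named in ``accession_map`` for a supplied sample must have at least one
    replicate; an accession mentioned in the map with no matching call set is
    an error only if no call set at all maps to it.
    """
    by_accession: dict[str, list[CytosineCallSet]] = {}
    for cs in calls:
        if cs.sample_id not in accession_map:
            raise KeyError(f"sample {cs.sample_id!r} has no accession assignment")
        by_accession.setdefault(accession_map[cs.sample_id], []).append(cs)
    mapped_accessions = set(accession_map.values())
    empty = mapped_accessions - set(by_accession)
    if empty:
        raise ValueError(f"accessions with zero replicates: {sorted(empty)}")

    pooled: dict[str, CytosineCallSet] = {}
    for accession, replicates in by_accession.items():
        if len(replicates) == 1:
            d = replicates[0].data
        else:
            cat = pd.concat([r.data for r in replicates], ignore_index=True)
            d = (
                cat.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=False)[
                    ["meth", "total"]
                ]
                .sum()
                .loc[:, ["chrom", "pos", "strand", "meth", "total", "context"]]
            )
        pooled[accession] = CytosineCallSet(sample_id=accession, data=d.copy())
    return pooled


def window_proportions(
    pooled: dict[str, CytosineCallSet],
    window_size: int = 200,
    min_reads: int = 10,
) -> WindowMethylationMatrix:
    """Bin pooled CG counts into fixed windows and score pooled-read proportions.

    Windows are non-overlapping, anchored at coordinate 0, 0-based half-open
    ``[k*window_size, (k+1)*window_size)``; the 1-based report positions are
    shifted down by one before binning.  A window's value for an accession is
    missing when its pooled coverage is below ``min_reads``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if not pooled:
        raise ValueError("no accessions supplied")

    per_acc: dict[str, pd.DataFrame] = {}
    for accession, cs in pooled.items():
        d = cs.data
        d = d.loc[d["context"] == "CG"]
        pos0 = d["pos"].to_numpy() - 1
        start = (pos0 // window_size) * window_size
        key = d["chrom"].astype(str) + ":" + pd.Series(start, index=d.index).astype(str)
        agg = d.groupby(key.values)[["meth", "total"]].sum()
        per_acc[accession] = agg

    all_windows = sorted(
        set().union(*(set(a.index) for a in per_acc.values())),
        key=lambda k: (k.rsplit(":", 1)[0], int(k.rsplit(":", 1)[1])),
    )
    accs = sorted(per_acc)
    meth = pd.DataFrame(0, index=accs, columns=all_windows, dtype=int)
    total = pd.DataFrame(0, index=accs, columns=all_windows, dtype=int)
    for accession, agg in per_acc.items():
        meth.loc[accession, agg.index] = agg["meth"].to_numpy()
        total.loc[accession, agg.index] = agg["total"].to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        props = meth.to_numpy(dtype=float) / total.to_numpy(dtype=float)
    props[total.to_numpy() < min_reads] = np.nan
    proportions = pd.DataFrame(props, index=accs, columns=all_windows)
    return WindowMethylationMatrix(
        proportions=proportions,
        coverage=total,
        meth_counts=meth,
        window_size=window_size,
        min_reads=min_reads,
    )


def filter_windows(
    q: WindowMethylationMatrix,
    max_missing_frac: float = 0.5,
) -> WindowMethylationMatrix:
    """Drop windows missing in more than ``max_missing_frac`` of accessions or
    with no methylated read at all.

    "More than" is strict: a window missing in exactly half the accessions is
    retained.  The methylated-read rule counts reads over all accessions,
    including cells below the coverage threshold.
    """
    missing_frac = q.proportions.isna().mean(axis=0)
    any_meth = q.meth_counts.sum(axis=0) > 0
    keep_missing = missing_frac <= max_missing_frac
    keep = keep_missing & any_meth
    n_missing_fail = int((~keep_missing).sum())
    n_meth_fail = int((keep_missing & ~any_meth).sum())
    logger.info(
        "window filter: %d input, %d failed missingness rule, %d failed methylated-read rule, %d retained",
        q.n_windows, n_missing_fail, n_meth_fail, int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("all windows removed by filtering")
    cols = q.proportions.columns[keep.to_numpy()]
    return WindowMethylationMatrix(
        proportions=q.proportions.loc[:, cols],
        coverage=q.coverage.loc[:, cols],
        meth_counts=q.meth_counts.loc[:, cols],
        window_size=q.window_size,
        min_reads=q.min_reads,
    )


def similarity_matrix(q: WindowMethylationMatrix) -> SimilarityStructure:
    """Standardize window columns and form M = QQ'/N with pairwise-complete N.

    Columns are centered and scaled to unit *population* variance over their
    observed entries (so trace(M)/n = 1 exactly under complete data); missing
    cells then contribute 0 to the cross-product.  Zero-variance windows are
    dropped with a warning; a pair of accessions with no co-observed window is
    an error.
    """
    labels = q.accession_labels
    if len(labels) < 2:
        raise ValueError("similarity matrix needs at least two accessions")
    x = q.proportions.to_numpy(dtype=float)
    observed = ~np.isnan(x)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(x, axis=0)
        var = np.nanvar(x, axis=0)  # population variance (ddof=0)
    nonconstant = var > 0
    n_dropped = int((~nonconstant).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} zero-variance windows before standardization", stacklevel=2)
    x = x[:, nonconstant]
    observed = observed[:, nonconstant]
    mean = mean[nonconstant]
    sd = np.sqrt(var[nonconstant])

    z = (x - mean[None, :]) / sd[None, :]
    z[~observed] = 0.0

    n_shared = observed.astype(np.int64) @ observed.astype(np.int64).T
    if np.any(n_shared == 0):
        i, j = np.argwhere(n_shared == 0)[0]
        raise ValueError(f"accessions {labels[i]!r} and {labels[j]!r} share no observed window")
    m = (z @ z.T) / n_shared
    return SimilarityStructure(m=m, n_shared=n_shared, labels=labels)
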