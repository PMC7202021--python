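"""Genomic relatedness from homozygous clone-group SNP profiles.

Highly selfing lines are effectively fully homozygous, so each biallelic SNP
is coded 0/1 (homozygous reference / homozygous alternate) rather than the
0/1/2 dosage used for outbred diploids.  Under that coding the variance of a
genotype at sample allele frequency p is p(1-p), and the relatedness matrix

    G = W W' / sum_j p_j (1 - p_j),      W_ij = x_ij - p_j

is the cross-product of frequency-centered genotypes scaled so that its mean
diagonal is ~1 for frequency-matched random genotypes.  This is the
homozygosity-adjusted analogue of the usual centered-genotype kinship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._linalg import bend_psd, is_symmetric, symmetrize

logger = logging.getLogger(__name__)

__all__ = ["SnpMatrix", "CovarianceStructure", "filter_snps", "center_genotypes", "compute_grm"]


@dataclass
class SnpMatrix:
    """Clone-group x SNP genotype codes in {0, 1, NaN} (homozygous calls only)."""

    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genotypes
        if g.index.has_duplicates:
            dups = g.index[g.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate clone-group labels: {dups}")
        vals = g.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            offending = sorted({float(v) for v in vals[bad]})
            raise ValueError(
                f"genotype codes must be 0, 1 or missing (homozygous coding); found {offending}"
            )
        self.genotypes = g.astype(float)

    @property
    def group_labels(self) -> list[str]:
        return [str(x) for x in self.genotypes.index]

    @property
    def snp_ids(self) -> list[str]:
        return [str(x) for x in self.genotypes.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.genotypes.shape

    @property
    def allele_freq(self) -> np.ndarray:
        """Sample frequency of the '1' allele per SNP, from non-missing calls."""
        return self.genotypes.mean(axis=0, skipna=True).to_numpy()

    @property
    def n_missing(self) -> np.ndarray:
        return self.genotypes.isna().sum(axis=0).to_numpy()


@dataclass
class CovarianceStructure:
    """A labelled symmetric relatedness/similarity matrix (G or M)."""

    values: np.ndarray
    labels: list[str]
    kind: str = "genomic"
    psd_adjusted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariance structure contains non-finite entries")
        if not is_symmetric(self.values):
            raise ValueError("covariance structure is not symmetric")
        self.values = symmetrize(self.values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def bend(self, floor_factor: float = 1e-6) -> "CovarianceStructure":
        """Return a PSD-bent copy (eigenvalue floor); no-op if already PSD."""
        bent, adjusted = bend_psd(self.values, floor_factor)
        if not adjusted:
            return self
        return replace(self, values=bent, psd_adjusted=True)


@dataclass
class SnpFilterLog:
    n_input: int
    n_monomorphic: int
    n_too_missing: int
    n_retained: int


def filter_snps(
    snps: SnpMatrix,
    min_minor_copies: int = 1,
    max_missing: int = 1,
) -> SnpMatrix:
    """Keep SNPs with >= ``min_minor_copies`` of the minor allele and <= ``max_missing`` no-calls.

    The minor-allele count is the smaller of the 0 and 1 counts among
    non-missing calls, so monomorphic columns (zero copies) are always removed
    under the default.  The per-rule removal counts are logged and attached to
    the returned matrix as ``filter_log``.
    """
    g = snps.genotypes
    vals = g.to_numpy(dtype=float)
    n_missing = np.isnan(vals).sum(axis=0)
    n_alt = np.nansum(vals, axis=0)
    n_called = vals.shape[0] - n_missing
    minor_copies = np.minimum(n_alt, n_called - n_alt)

    poly_ok = minor_copies >= min_minor_copies
    missing_ok = n_missing <= max_missing
    keep = poly_ok & missing_ok

    log = SnpFilterLog(
        n_input=g.shape[1],
        n_monomorphic=int((~poly_ok).sum()),
        n_too_missing=int((~missing_ok).sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "SNP filter: %d input, %d failed minor-allele rule, %d failed missingness rule, %d retained",
        log.n_input, log.n_monomorphic, log.n_too_missing, log.n_retained,
    )
    if log.n_retained == 0:
        raise ValueError("no SNPs survive filtering; relatedness matrix is undefined")
    out = SnpMatrix(g.loc[:, keep])
    out.filter_log = log  # type: ignore[attr-defined]
    return out


def center_genotypes(snps: SnpMatrix, p: np.ndarray | None = None) -> np.ndarray:
    """Center genotypes by allele frequency: W_ij = x_ij - p_j.

    ``p`` defaults to the sample allele frequency over non-missing calls, in
    which case each column of W sums to zero.  Missing cells are set to 0
    (mean imputation), the standard choice for sparse missingness.
    """
    vals = snps.genotypes.to_numpy(dtype=float)
    if p is None:
        p = snps.allele_freq
    p = np.asarray(p, dtype=float)
    if p.shape != (vals.shape[1],):
        raise ValueError("allele-frequency vector length does not match SNP count")
    w = vals - p[None, :]
    w[np.isnan(w)] = 0.0
    return w


def compute_grm(
    w: np.ndarray,
    p: np.ndarray,
    labels: list[str] | None = None,
) -> CovarianceStructure:
    """G = W W' / sum_j p_j (1 - p_j) for homozygous 0/1 genotypes."""
    w = np.asarray(w, dtype=float)
    p = np.asarray(p, dtype=float)
    denom = float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("sum p(1-p) is zero: all SNPs are fixed, G is undefined")
    g = (w @ w.T) / denom
    if labels is None:
        labels = [str(i) for i in range(w.shape[0])]
    return CovarianceStructure(values=g, labels=list(labels), kind="genomic")


def grm_from_snps(snps: SnpMatrix, min_minor_copies: int = 1, max_missing: int = 1) -> CovarianceStructure:
    """Convenience pipeline: filter -> center -> cross-product scaling."""
    filtered = filter_snps(snps, min_minor_copies=min_minor_copies, max_missing=max_missing)
    w = center_genotypes(filtered)
    return compute_grm(w, filtered.allele_freq, labels=filtered.group_labels)
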