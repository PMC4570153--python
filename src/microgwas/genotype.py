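"""Genotype QC and population-structure estimation.

Additively coded genotype matrices (0/1/2 alternate-allele counts, -1 for
missing), SNP filtering on minor allele frequency, exact Hardy-Weinberg
equilibrium, missingness and autosome membership, pairwise identity-by-state
(IBS), and classical (Torgerson) metric multidimensional scaling of the
resulting distance matrix.  These are the stratification controls used before
any trait association is attempted: the leading MDS coordinates of the IBS
matrix summarise genetic ancestry and enter downstream models as covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QcThresholds",
    "DistanceMatrix",
    "compute_maf",
    "minor_allele_frequencies",
    "hwe_exact_test",
    "filter_snps",
    "allele_frequency_spectrum",
    "ibs_matrix",
    "classical_mds",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive genotypes with per-SNP metadata.

    Parameters
    ----------
    values : ndarray of int8, shape (n_individuals, n_snps)
        Count of alternate alleles; ``MISSING`` (-1) marks a no-call.
    snp_meta : DataFrame
        One row per SNP with columns ``id``, ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``.  Positions must be strictly increasing within each
        chromosome.
    individual_ids : list of str
    """

    values: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x SNPs)")
        bad = ~np.isin(self.values, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype values must be in {0, 1, 2, missing}")
        if len(self.snp_meta) != self.values.shape[1]:
            raise ValueError("snp_meta rows must match number of SNP columns")
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValueError("individual_ids must match number of rows")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        for _, sub in self.snp_meta.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(
                    "SNP positions must be strictly increasing within chromosome"
                )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.values[:, idx],
            self.snp_meta.iloc[idx].reset_index(drop=True),
            list(self.individual_ids),
        )

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx, :],
            self.snp_meta,
            [self.individual_ids[i] for i in idx],
        )


@dataclass(frozen=True)
class QcThresholds:
    """SNP retention thresholds; all boundaries are strict.

    A SNP is kept when MAF > ``maf_min``, exact-HWE P > ``hwe_p_min``,
    missing fraction < ``max_missing``, and (if ``autosomal_only``) its
    chromosome is 1..22 after stripping an optional ``chr`` prefix.
    """

    maf_min: float = 0.10
    hwe_p_min: float = 1e-3
    max_missing: float = 0.5
    autosomal_only: bool = True

    def __post_init__(self):
        for name in ("maf_min", "hwe_p_min", "max_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class DistanceMatrix:
    """Labelled symmetric pairwise matrix, either a similarity or a distance."""

    labels: list
    values: np.ndarray
    kind: str = "distance"  # or "similarity"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match number of labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if self.kind not in ("distance", "similarity"):
            raise ValueError("kind must be 'distance' or 'similarity'")

    def to_distance(self) -> "DistanceMatrix":
        """Similarity s in [0,1] converts to distance 1 - s."""
        if self.kind == "distance":
            return self
        return DistanceMatrix(list(self.labels), 1.0 - self.values, "distance")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# allele frequencies


def compute_maf(genotypes) -> float:
    """Minor allele frequency of one SNP.

    ``min(p, 1 - p)`` with p the alternate-allele frequency over non-missing
    genotypes.  Raises if every genotype is missing.
    """
    g = np.asarray(genotypes)
    ok = g != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    p = g[ok].sum() / (2.0 * n)
    return float(min(p, 1.0 - p))


def minor_allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Vectorised per-SNP MAF; NaN where a SNP has no non-missing calls."""
    g = matrix.values
    ok = g != MISSING
    n = ok.sum(axis=0)
    alt = np.where(ok, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return np.where(np.isnan(p), np.nan, np.minimum(p, 1.0 - p))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium P value.

    Conditions on the observed allele counts and enumerates every attainable
    heterozygote count, summing the probabilities of all genotype
    configurations no more probable than the observed one (the standard
    conditional exact test for HWE).  Probabilities follow the recurrence

        P(het = h + 2) / P(het = h) = hom_ref(h) * hom_alt(h) * 4
                                      / ((h + 2) * (h + 1))

    evaluated from the modal heterozygote count for numerical stability.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    # rare allele count; by symmetry use the smaller of the two alleles
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable configuration

    # attainable heterozygote counts share the parity of n_rare
    h_min = n_rare % 2
    h_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(h_min, h_max + 1, 2)

    # unnormalised probabilities via the ratio recurrence, anchored at the
    # largest term to avoid under/overflow
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i - 1]
        hom_rare = (n_rare - h) // 2
        hom_common = (2 * n - n_rare - h) // 2
        logp[i] = logp[i - 1] + np.log(4.0 * hom_rare * hom_common) - np.log(
            (h + 2.0) * (h + 1.0)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()

    obs = n_Aa
    p_obs = probs[(hets == obs).argmax()] if obs in hets else 0.0
    # sum configurations with probability <= observed (small tolerance for
    # floating-point ties)
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# filtering


def _is_autosomal(chroms) -> np.ndarray:
    out = []
    for c in chroms:
        s = str(c)
        if s.lower().startswith("chr"):
            s = s[3:]
        out.append(s.isdigit() and 1 <= int(s) <= 22)
    return np.asarray(out, dtype=bool)


def filter_snps(matrix: GenotypeMatrix, thresholds: QcThresholds):
    """Apply all QC filters; return the retained matrix and a removal report.

    The report counts, per filter, how many SNPs fail that filter (a SNP
    failing several is counted under each) plus the joint removal count.
    SNP order is preserved.
    """
    g = matrix.values
    n_ind = matrix.n_individuals
    maf = minor_allele_frequencies(matrix)

    fail_maf = ~(maf > thresholds.maf_min)  # NaN MAF (all-missing) fails too

    hwe_p = np.ones(matrix.n_snps)
    for j in range(matrix.n_snps):
        col = g[:, j]
        col = col[col != MISSING]
        if len(col) == 0:
            hwe_p[j] = np.nan
            continue
        n_aa = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        hwe_p[j] = hwe_exact_test(n_AA, n_het, n_aa)
    fail_hwe = ~(hwe_p > thresholds.hwe_p_min)

    miss_frac = (g == MISSING).mean(axis=0) if n_ind else np.zeros(matrix.n_snps)
    fail_miss = ~(miss_frac < thresholds.max_missing)

    if thresholds.autosomal_only:
        fail_auto = ~_is_autosomal(matrix.snp_meta["chrom"])
    else:
        fail_auto = np.zeros(matrix.n_snps, dtype=bool)

    keep = ~(fail_maf | fail_hwe | fail_miss | fail_auto)
    report = {
        "n_input": int(matrix.n_snps),
        "fail_maf": int(fail_maf.sum()),
        "fail_hwe": int(fail_hwe.sum()),
        "fail_missing": int(fail_miss.sum()),
        "fail_autosomal": int(fail_auto.sum()),
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
        "empty_output": bool(keep.sum() == 0),
    }
    if report["empty_output"]:
        warnings.warn("all SNPs removed by QC filters", stacklevel=2)
    return matrix.take_snps(np.where(keep)[0]), report


def allele_frequency_spectrum(matrix: GenotypeMatrix) -> np.ndarray:
    """Folded site-frequency spectrum: histogram of minor-allele counts.

    Bin k holds the number of SNPs whose minor allele appears exactly k times
    among non-missing genotypes.  Empty input yields an empty histogram.
    """
    if matrix.n_snps == 0:
        return np.zeros(0, dtype=int)
    g = matrix.values
    ok = g != MISSING
    n = ok.sum(axis=0)
    alt = np.where(ok, g, 0).sum(axis=0)
    mac = np.minimum(alt, 2 * n - alt)
    return np.bincount(mac[n > 0])


# ---------------------------------------------------------------------------
# identity-by-state


def ibs_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise identity-by-state similarity.

    IBS(i, j) = mean over SNPs non-missing in both individuals of
    (2 - |g_i - g_j|) / 2; the diagonal is 1.  Pairs sharing no genotyped
    SNP get NaN with a warning.  Computed with one-hot matrix products so the
    cost is a handful of (n x m) matmuls.
    """
    if matrix.n_individuals < 2:
        raise ValueError("IBS requires at least 2 individuals")
    g = matrix.values
    valid = (g != MISSING).astype(np.float64)
    a = [(g == k).astype(np.float64) for k in (0, 1, 2)]

    shared = valid @ valid.T
    # sum over shared SNPs of |g_i - g_j|
    diff1 = a[0] @ a[1].T + a[1] @ a[0].T + a[1] @ a[2].T + a[2] @ a[1].T
    diff2 = a[0] @ a[2].T + a[2] @ a[0].T
    absdiff = diff1 + 2.0 * diff2

    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - absdiff / (2.0 * shared)
    if (shared == 0).any():
        warnings.warn("pairs with zero shared genotyped SNPs: IBS undefined (NaN)",
                      stacklevel=2)
    np.fill_diagonal(ibs, 1.0)
    ibs = (ibs + ibs.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(list(matrix.individual_ids), ibs, "similarity")


# ---------------------------------------------------------------------------
# classical (Torgerson) MDS


def classical_mds(dist: DistanceMatrix, k: int):
    """Classical metric MDS (principal coordinates) of a distance matrix.

    Double-centres the squared distances, eigendecomposes the resulting Gram
    matrix, and returns the first ``k`` coordinates (eigenvectors scaled by
    the square root of their eigenvalues) ordered by decreasing eigenvalue.
    A similarity input is first converted via ``1 - s``.  The sign of each
    axis is fixed so that its largest-magnitude loading is positive.

    Returns ``(coords, eigenvalues)`` with ``coords`` shaped
    (n_points, k) and ``eigenvalues`` the full spectrum (descending).
    """
    dm = dist.to_distance()
    d = dm.values
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")

    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    tol = max(n, 1) * np.abs(evals).max() * 1e-12 if evals.size else 0.0
    n_pos = int((evals > tol).sum())
    if k > n_pos:
        raise ValueError(
            f"requested k={k} exceeds the {n_pos} positive eigenvalues; "
            f"attainable k <= {n_pos}"
        )
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    # deterministic sign: largest-|loading| entry of each axis made positive
    for a in range(k):
        i = int(np.abs(coords[:, a]).argmax())
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    return coords, evals
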