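"""SNP->gene mapping and fold-enrichment statistics.

Associated SNPs are mapped to genes whose interval overlaps or lies within a
window (default 50 kb, boundary inclusive) of the SNP position.  The
resulting query set is compared against an externally scored universe (a
GWAS-catalog-like table of (id, P) pairs) with a fold-enrichment curve over
P-value cutoffs: at cutoff P_i the observed overlap with the significant set
G_i is divided by the overlap expected at the background rate, where the
background rate is the query's overlap fraction among ids NOT in G_i.
Fisher's exact test quantifies overlap between two discrete sets within a
universe, and a full factorial sweep over P-value and distance cutoffs
probes the sensitivity of the enrichment to those arbitrary choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneAnnotation",
    "map_snps_to_genes",
    "select_correlated_snps",
    "fold_enrichment_curve",
    "fisher_overlap_test",
    "cutoff_sensitivity_sweep",
]


class GeneAnnotation:
    """Gene intervals in 0-based half-open coordinates with unique names."""

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "start", "end", "name"}
        if not required <= set(table.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        t = table.copy()
        t["chrom"] = t["chrom"].map(_norm_chrom)
        if (t["start"] >= t["end"]).any():
            raise ValueError("gene intervals must satisfy start < end")
        if t["name"].duplicated().any():
            raise ValueError("gene names must be unique")
        self.table = t.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self):
        return len(self.table)

    @property
    def names(self):
        return list(self.table["name"])


def _norm_chrom(c) -> str:
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


def map_snps_to_genes(snps: pd.DataFrame, annotation: GeneAnnotation, max_dist: int):
    """Assign each SNP every gene within ``max_dist`` bp (inclusive).

    ``snps`` needs columns (id, chrom, pos) with 1-based positions.  The
    distance from a SNP to a gene interval is 0 when the SNP falls inside
    the half-open interval, otherwise the gap in base pairs to the nearest
    interval edge.  A SNP may hit several genes; the returned gene set is
    deduplicated.  SNP chromosomes absent from the annotation raise a
    reconciliation error listing the unmatched labels.

    Returns ``(gene set, per-SNP dict of gene name lists)``.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    ann = annotation.table
    snp_chroms = {_norm_chrom(c) for c in snps["chrom"]}
    unmatched = sorted(snp_chroms - set(ann["chrom"]))
    if unmatched:
        raise ValueError(
            f"SNP chromosomes not present in the annotation: {unmatched}"
        )
    per_snp: dict = {}
    genes: set = set()
    by_chrom = {c: sub for c, sub in ann.groupby("chrom")}
    for sid, chrom, pos in zip(snps["id"], snps["chrom"], snps["pos"]):
        sub = by_chrom[_norm_chrom(chrom)]
        p0 = int(pos) - 1  # 0-based point
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        dist = np.where(
            p0 < start, start - p0, np.where(p0 >= end, p0 - (end - 1), 0)
        )
        hit = sub["name"].to_numpy()[dist <= max_dist]
        per_snp[sid] = list(hit)
        genes.update(hit)
    return genes, per_snp


def select_correlated_snps(results: pd.DataFrame, p_cutoff: float) -> set:
    """SNPs associated with at least one trait at P <= cutoff (inclusive)."""
    ok = results["P"] <= p_cutoff
    return set(results.loc[ok.fillna(False), "SNP"])


def fold_enrichment_curve(query, scored_universe: pd.DataFrame, cutoffs) -> pd.DataFrame:
    """Fold enrichment of a query set over P-value cutoffs.

    For each cutoff P_i: G_i = {id : p <= P_i}; observed = |M ∩ G_i|; the
    background rate r = |M ∩ (U \\ G_i)| / |U \\ G_i| scales to expected =
    r |G_i|; fold = observed / expected.  Cutoffs where G_i is empty, the
    background is empty, or the background overlap is zero are flagged
    undefined (NaN fold) rather than dropped.  The raw background overlap
    count is emitted alongside for transparency.
    """
    ids = scored_universe["id"].to_numpy()
    p = scored_universe["p"].to_numpy(dtype=float)
    universe = set(ids)
    m = set(query)
    missing = sorted(m - universe)
    if missing:
        raise ValueError(f"query ids not in universe: {missing[:10]}")
    in_m = np.array([i in m for i in ids])

    rows = []
    for ci in cutoffs:
        g_i = p <= ci
        n_g = int(g_i.sum())
        n_bg = int((~g_i).sum())
        observed = int((g_i & in_m).sum())
        bg_overlap = int(((~g_i) & in_m).sum())
        if n_g == 0 or n_bg == 0 or bg_overlap == 0:
            rows.append((ci, observed, np.nan, np.nan, n_g, bg_overlap, True))
            continue
        rate = bg_overlap / n_bg
        expected = rate * n_g
        rows.append((ci, observed, expected, observed / expected, n_g, bg_overlap,
                     False))
    return pd.DataFrame(
        rows,
        columns=["cutoff", "observed", "expected", "fold", "n_significant",
                 "background_overlap", "undefined"],
    ).assign(universe_size=len(ids))


def fisher_overlap_test(set_a, set_b, universe):
    """Two-sided Fisher's exact test for overlap of two sets in a universe.

    Builds the 2x2 membership table and sums hypergeometric probabilities of
    all tables no more probable than the observed one.

    Returns ``(odds_ratio, p_value)``.
    """
    u = set(universe)
    if not u:
        raise ValueError("universe must be non-empty")
    a, b = set(set_a), set(set_b)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(u) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return float(odds), float(p)


def cutoff_sensitivity_sweep(
    results: pd.DataFrame,
    p_cutoffs,
    dist_cutoffs,
    annotation: GeneAnnotation,
    query_db: pd.DataFrame,
    query_cutoffs=(0.05,),
) -> pd.DataFrame:
    """Full factorial sweep over association-P and gene-distance cutoffs.

    For every (p_cutoff, dist_cutoff): select SNPs at the association
    cutoff, map them to genes within the distance window, and score the
    resulting gene set against the scored query universe at each query
    cutoff with the fold-enrichment statistic.  One row per
    (p_cutoff, dist_cutoff, query_cutoff).
    """
    snp_meta = results[["SNP", "CHR", "BP"]].drop_duplicates("SNP")
    rows = []
    for pc in p_cutoffs:
        sel = select_correlated_snps(results, pc)
        snps = snp_meta[snp_meta["SNP"].isin(sel)].rename(
            columns={"SNP": "id", "CHR": "chrom", "BP": "pos"}
        )
        for dc in dist_cutoffs:
            gene_set, _ = map_snps_to_genes(snps, annotation, dc)
            gene_set = gene_set & set(query_db["id"])
            curve = fold_enrichment_curve(gene_set, query_db, query_cutoffs)
            for _, r in curve.iterrows():
                rows.append(
                    (pc, dc, r["cutoff"], len(sel), len(gene_set), r["observed"],
                     r["expected"], r["fold"], bool(r["undefined"]))
                )
    return pd.DataFrame(
        rows,
        columns=["p_cutoff", "dist_cutoff", "query_cutoff", "n_snps", "n_genes",
                 "observed", "expected", "fold", "undefined"],
    )
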