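"""Microbiome quantitative-trait construction.

Turns a samples x taxa abundance table into the quantitative traits used for
host-genotype association: genus-level collapsed relative abundances, Shannon
alpha diversity, Bray-Curtis beta diversity, and the leading principal
coordinates of the beta-diversity matrix ("microbiome PCs").  A prevalence /
abundance / inter-correlation filter reduces the taxon set before abundances
are used as traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .genotype import DistanceMatrix, classical_mds

__all__ = [
    "RANKS",
    "TraitMatrix",
    "collapse_taxa",
    "normalize_relative_abundance",
    "filter_taxa",
    "alpha_diversity",
    "beta_diversity",
    "microbiome_pcs",
    "correlate_pcs_with_taxa",
]

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
_PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__", "s__"]


@dataclass
class TraitMatrix:
    """Samples x traits values with a provenance tag.

    provenance is one of ``microbiome_pc``, ``taxon_abundance``,
    ``alpha_diversity``.
    """

    data: pd.DataFrame
    provenance: str = "taxon_abundance"

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("one row per sample required")


def _parse_lineage(lineage: str, taxon: str) -> list:
    parts = [p.strip() for p in str(lineage).split(";")]
    for i, part in enumerate(parts):
        if i >= len(_PREFIXES) or not part.startswith(_PREFIXES[i]):
            raise ValueError(
                f"malformed lineage for taxon {taxon!r}: segment {i} is {part!r}"
            )
    return parts


def collapse_taxa(table: pd.DataFrame, taxonomy: pd.Series, rank: str = "genus"):
    """Sum abundances of taxa sharing a lineage prefix up to ``rank``.

    Taxa unclassified at the requested rank (empty name, e.g. ``g__``) are
    collapsed to their deepest classified ancestor, so a family-only OTU
    still yields one family-level trait ("genus level or above").

    Returns ``(collapsed table, collapsed taxonomy)``.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    depth = RANKS.index(rank)
    keys = {}
    for taxon in table.columns:
        parts = _parse_lineage(taxonomy.loc[taxon], taxon)
        kept = []
        for i, part in enumerate(parts[: depth + 1]):
            if len(part) <= len(_PREFIXES[i]):  # unclassified at this level
                break
            kept.append(part)
        if not kept:
            raise ValueError(f"taxon {taxon!r} unclassified at every rank")
        keys[taxon] = ";".join(kept)
    grouped = table.T.groupby(table.columns.map(keys)).sum().T
    new_tax = pd.Series({v: v for v in grouped.columns}, name="lineage")
    grouped.attrs = dict(table.attrs)
    return grouped, new_tax


def normalize_relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Close each sample to relative abundance (rows sum to 1).

    Samples with zero total are removed with a warning.
    """
    totals = table.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"removing {int(zero.sum())} zero-total sample(s): "
            f"{list(table.index[zero])}",
            stacklevel=2,
        )
        table = table.loc[~zero]
        totals = totals[~zero]
    out = table.div(totals, axis=0)
    out.attrs = dict(table.attrs)
    return out


def filter_taxa(
    table: pd.DataFrame,
    prevalence_min: float = 0.1,
    abundance_min: float = 1e-4,
    cor_max: float = 0.95,
):
    """Prevalence/abundance floors, then greedy de-correlation.

    A taxon must be present (abundance > 0) in at least ``prevalence_min`` of
    samples and have mean relative abundance >= ``abundance_min``.  Then,
    while any taxon pair has Spearman correlation > ``cor_max``, the member
    with lower prevalence (ties: lower mean abundance, then name) is dropped.

    Returns ``(filtered table, removal log)`` where the log is a list of
    ``(taxon, reason)`` tuples; its length always matches the number of
    columns removed.
    """
    log = []
    prevalence = (table > 0).mean(axis=0)
    mean_ab = table.mean(axis=0)
    keep = []
    for t in table.columns:
        if prevalence[t] < prevalence_min:
            log.append((t, f"prevalence {prevalence[t]:.3f} < {prevalence_min}"))
        elif mean_ab[t] < abundance_min:
            log.append((t, f"mean abundance {mean_ab[t]:.2e} < {abundance_min}"))
        else:
            keep.append(t)
    sub = table[keep]

    if len(keep) >= 2 and cor_max < 1:
        rho = pd.DataFrame(
            spearmanr(sub.to_numpy())[0] if len(keep) > 2
            else [[1.0, spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])[0]],
                  [spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])[0], 1.0]],
            index=keep,
            columns=keep,
        ).abs()
        np.fill_diagonal(rho.values, 0.0)
        while True:
            m = np.nanmax(rho.values) if rho.size else 0.0
            if not m > cor_max:
                break
            i, j = np.unravel_index(np.nanargmax(rho.values), rho.shape)
            a, b = rho.index[i], rho.columns[j]
            drop = min(
                (a, b),
                key=lambda t: (prevalence[t], mean_ab[t], t),
            )
            log.append((drop, f"spearman correlation {m:.3f} > {cor_max}"))
            rho = rho.drop(index=drop, columns=drop)
        sub = sub[list(rho.index)]
    out = sub.copy()
    out.attrs = dict(table.attrs)
    return out, log


def alpha_diversity(abundances, metric: str = "shannon") -> float:
    """Within-sample diversity; Shannon entropy H = -sum p ln p."""
    if metric != "shannon":
        raise ValueError(f"unsupported alpha metric {metric!r}")
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any() or x.sum() <= 0:
        raise ValueError("abundances must be non-negative with positive total")
    p = x / x.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def beta_diversity(table: pd.DataFrame, metric: str = "bray_curtis") -> DistanceMatrix:
    """Between-sample dissimilarity matrix.

    Bray-Curtis: BC(i,j) = 1 - 2 sum_k min(x_ik, x_jk) / sum_k (x_ik + x_jk).
    Pairs of all-zero samples are undefined and flagged NaN with a warning.
    """
    if metric != "bray_curtis":
        raise ValueError(f"unsupported beta metric {metric!r}")
    if len(table) < 2:
        raise ValueError("beta diversity requires >= 2 samples")
    x = table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    zero = x.sum(axis=1) == 0
    if zero.any():
        warnings.warn("all-zero samples give undefined Bray-Curtis entries",
                      stacklevel=2)
        d[np.ix_(zero, zero)] = np.nan
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.index), d, "distance")


def microbiome_pcs(
    table_or_distance, k: int = 5, metric: str = "bray_curtis",
    body_site: str | None = None,
) -> TraitMatrix:
    """First ``k`` principal coordinates of the beta-diversity matrix.

    Accepts either an abundance table (Bray-Curtis computed internally) or a
    pre-computed DistanceMatrix (e.g. a user-supplied UniFrac).  Coordinates
    are computed by classical MDS, shared with the host-genotype machinery.
    Trait names are ``{site}|PC{i}`` when a body site is known.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(table_or_distance, DistanceMatrix):
        dm = table_or_distance
    else:
        if body_site is None:
            body_site = table_or_distance.attrs.get("body_site")
        dm = beta_diversity(table_or_distance, metric=metric)
    coords, _ = classical_mds(dm, k)
    prefix = f"{body_site}|" if body_site else ""
    cols = [f"{prefix}PC{i + 1}" for i in range(k)]
    return TraitMatrix(
        pd.DataFrame(coords, index=dm.labels, columns=cols),
        provenance="microbiome_pc",
    )


def correlate_pcs_with_taxa(table: pd.DataFrame, pcs: TraitMatrix) -> pd.DataFrame:
    """Spearman correlation of every taxon with every principal coordinate.

    Returns a tidy frame (taxon, pc, rho, p, top) where ``top`` marks the
    most strongly correlated taxon per PC.  Constant taxa get NaN rho and a
    flag rather than an error.
    """
    common = table.index.intersection(pcs.data.index)
    tab = table.loc[common]
    rows = []
    for pc in pcs.data.columns:
        y = pcs.data.loc[common, pc]
        for taxon in tab.columns:
            x = tab[taxon]
            if x.nunique() <= 1:
                rows.append((taxon, pc, np.nan, np.nan, False))
                continue
            rho, p = spearmanr(x, y)
            rows.append((taxon, pc, rho, p, False))
    out = pd.DataFrame(rows, columns=["taxon", "pc", "rho", "p", "top"])
    for pc, sub in out.groupby("pc"):
        if sub["rho"].notna().any():
            out.loc[sub["rho"].abs().idxmax(), "top"] = True
    return out
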