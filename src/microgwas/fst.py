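"""Population differentiation of microbiome-linked SNPs.

Compares the median F_ST of SNPs associated with microbiome traits against
the genome-wide background, per body site and population pair.  Significance
comes from a permutation test on the difference of medians (pooled values
randomly re-split at the original group sizes, 10,000 rounds by default) and
uncertainty on the group median from a bootstrap percentile confidence
interval.  P values use the add-one correction (k + 1)/(B + 1) so a result
can never be exactly zero, which keeps the downstream Benjamini-Hochberg
step well defined; the smallest attainable P is therefore 1/(B + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import bh_fdr

__all__ = [
    "select_linked_snps",
    "permutation_median_test",
    "bootstrap_median_ci",
    "fst_comparison_table",
]

_PERM_CHUNK = 500  # permutations per vectorised block, bounds memory


def select_linked_snps(
    results: pd.DataFrame, p_cutoff: float = 1e-4, body_site: str | None = None
) -> set:
    """SNPs associated with any trait at P strictly below the cutoff.

    The boundary is exclusive: a test at exactly the cutoff is not linked.
    With ``body_site`` given, only traits named ``{site}|...`` count.
    """
    sub = results
    if body_site is not None:
        sub = sub[sub["TRAIT"].str.startswith(f"{body_site}|")]
    ok = sub["P"] < p_cutoff
    return set(sub.loc[ok.fillna(False), "SNP"])


def permutation_median_test(
    group,
    background,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "greater",
):
    """Permutation test on the difference of group medians.

    Pools both samples, repeatedly re-splits them at the original sizes, and
    compares each permuted median difference (group minus background) to the
    observed one.  ``alternative='greater'`` counts permutations whose
    difference strictly exceeds the observed (ties count as non-exceeding);
    ``'less'`` counts those strictly below.  P = (count + 1)/(n_perm + 1).

    Returns ``(p_value, observed_difference)``.
    """
    group = np.asarray(group, dtype=float)
    background = np.asarray(background, dtype=float)
    if len(group) == 0 or len(background) == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = float(np.median(group) - np.median(background))
    pool = np.concatenate([group, background])
    n_g = len(group)
    count = 0
    done = 0
    while done < n_perm:
        b = min(_PERM_CHUNK, n_perm - done)
        perm = rng.permuted(np.tile(pool, (b, 1)), axis=1)
        diffs = np.median(perm[:, :n_g], axis=1) - np.median(perm[:, n_g:], axis=1)
        if alternative == "greater":
            count += int((diffs > observed).sum())
        else:
            count += int((diffs < observed).sum())
        done += b
    p = (count + 1.0) / (n_perm + 1.0)
    return p, observed


def bootstrap_median_ci(
    values,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
    ci: float = 0.95,
):
    """Bootstrap percentile confidence interval for the median.

    Resamples with replacement at the original size, records each resample's
    median, and takes the (2.5, 97.5) percentiles of those medians (for the
    default 95 % level).

    Returns ``(ci_low, ci_high, median)``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("at least one value required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(values)
    meds = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(2 * _PERM_CHUNK, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        meds[done:done + b] = np.median(values[idx], axis=1)
        done += b
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(meds, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi), float(np.median(values))


def fst_comparison_table(
    scores: pd.DataFrame,
    linked_sets: dict,
    fdr_q: float = 0.05,
    p_flag_cutoff: float = 1e-3,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median-F_ST comparison for every (body site, population pair).

    ``scores`` holds columns (snp_id, population_pair, fst); ``linked_sets``
    maps body site -> set of linked SNP ids.  For each combination the
    linked group's median, its bootstrap CI, and permutation P values in
    both directions are computed against the disjoint background (all scored
    SNPs not in the linked set).  Benjamini-Hochberg Q values run across all
    comparisons per direction; rows are flagged significant at Q < ``fdr_q``
    (q_flag_*) and at P < ``p_flag_cutoff`` (p_flag_*).  Empty linked sets
    yield a flagged NaN row rather than being dropped.

    Every row records the seeds and resampling sizes used.
    """
    pairs = list(pd.unique(scores["population_pair"]))
    sites = list(linked_sets)
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(sites) * len(pairs))

    rows = []
    ci_idx = 0
    for site in sites:
        linked = set(linked_sets[site])
        for pair in pairs:
            sub = scores[scores["population_pair"] == pair]
            in_group = sub["snp_id"].isin(linked)
            group = sub.loc[in_group, "fst"].to_numpy()
            background = sub.loc[~in_group, "fst"].to_numpy()
            child = np.random.default_rng(children[ci_idx])
            ci_idx += 1
            if len(group) == 0:
                rows.append(
                    dict(body_site=site, population_pair=pair, n_group=0,
                         group_median=np.nan, background_median=np.nan,
                         ci_low=np.nan, ci_high=np.nan, p_higher=np.nan,
                         p_lower=np.nan, direction="undefined", empty_group=True)
                )
                continue
            p_hi, obs = permutation_median_test(
                group, background, n_perm=n_perm, seed=child, alternative="greater"
            )
            p_lo, _ = permutation_median_test(
                group, background, n_perm=n_perm, seed=child, alternative="less"
            )
            lo, hi, med = bootstrap_median_ci(group, n_boot=n_boot, seed=child)
            rows.append(
                dict(body_site=site, population_pair=pair, n_group=len(group),
                     group_median=med, background_median=float(np.median(background)),
                     ci_low=lo, ci_high=hi, p_higher=p_hi, p_lower=p_lo,
                     direction="higher" if obs > 0 else "lower",
                     empty_group=False)
            )
    out = pd.DataFrame(rows)
    out["q_higher"] = bh_fdr(out["p_higher"].to_numpy())
    out["q_lower"] = bh_fdr(out["p_lower"].to_numpy())
    out["q_flag_higher"] = out["q_higher"] < fdr_q
    out["q_flag_lower"] = out["q_lower"] < fdr_q
    out["p_flag_higher"] = out["p_higher"] < p_flag_cutoff
    out["p_flag_lower"] = out["p_lower"] < p_flag_cutoff
    out["n_perm"] = n_perm
    out["n_boot"] = n_boot
    out["seed"] = seed
    return out
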