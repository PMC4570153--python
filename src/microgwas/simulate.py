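"""Coupled genotype / microbiome / covariate / F_ST simulation.

The generator emulates the statistical structure of a small shotgun-derived
cohort: ~93 individuals drawn from a few differentiated populations
(Balding-Nichols genotypes at a target F_ST), compositional per-body-site
taxon abundances with a handful of taxa causally shifted by specific SNPs,
a covariate roster (sex, age, collection site, sequencing center, total
sequence count) optionally confounded with population, right-skewed per-SNP
F_ST scores with an optional median shift for trait-linked SNPs, and a
non-overlapping gene annotation.  Every output is a pure function of the
configuration and its seed: one master seed spawns named child streams in a
fixed order, so identical seeds give bit-identical datasets.

Known ground truth (which SNP drives which taxon, population labels, the
F_ST shift) is returned alongside the data so downstream stages can be
tested for null calibration and parameter recovery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix, hwe_exact_test

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_abundances",
    "simulate_covariates",
    "simulate_fst_scores",
    "make_gene_annotation",
    "simulate_dataset",
    "hudson_fst",
    "hudson_fst_genomewide",
]

_CENTERS = ["BCM", "BI", "JCVI", "WUGC"]
_SITES = ["houston", "stlouis"]

# order in which child seeds are drawn from the master SeedSequence
_STREAMS = ("genotypes", "covariates", "abundances", "fst", "genes")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the coupled simulation.

    Defaults mirror the cohort the package targets: 93 individuals from two
    populations at moderate differentiation (F_ST 0.1), SNPs across the MAF
    spectrum with sporadic missingness, 15 body sites of compositional
    abundance data, and a few SNP->taxon effects of 1.5 residual SD per
    alternate allele.
    """

    n_individuals: int = 93
    n_populations: int = 2
    n_snps: int = 1000
    fst_target: float = 0.1
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.05
    n_taxa: int = 50
    n_causal_pairs: int = 3
    effect_size: float = 1.5
    confound_strength: float = 0.0
    n_body_sites: int = 15
    count_depth: int | None = None  # multinomial read depth; None = fractions
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_snps < 1 or self.n_taxa < 1:
            raise ValueError("counts must be positive")
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
        for name in ("missing_rate", "confound_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_causal_pairs > min(self.n_snps, self.n_taxa):
            raise ValueError("n_causal_pairs must be <= min(n_snps, n_taxa)")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic child generator for one named component."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclass
class GroundTruth:
    """What the simulation planted, for downstream recovery checks."""

    causal_map: list = field(default_factory=list)  # (snp_id, taxon_id, effect)
    population_labels: list = field(default_factory=list)
    fst_shift: float = 0.0

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        d["causal_map"] = [tuple(x) for x in d["causal_map"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimulationConfig):
    """Balding-Nichols structured genotypes.

    Each SNP draws an ancestral frequency p ~ Uniform(maf_range); each
    population then draws its own frequency from
    Beta(p (1-F)/F, (1-p) (1-F)/F), which has mean p and variance
    F p (1-p) — the Balding-Nichols model at differentiation F.  At F = 0
    the Beta degenerates and every population shares p exactly.  Genotypes
    are Binomial(2, p_pop); entries are masked missing at ``missing_rate``.

    Returns ``(GenotypeMatrix, population_labels)``.
    """
    rng = config.rng("genotypes")
    n, m, npop = config.n_individuals, config.n_snps, config.n_populations
    f = config.fst_target

    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    if f == 0.0 or npop == 1:
        p_pop = np.tile(p_anc, (npop, 1))
    else:
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_pop = rng.beta(a, b, size=(npop, m))

    # near-equal population blocks, in individual order
    labels = np.repeat(np.arange(npop), int(np.ceil(n / npop)))[:n]
    geno = rng.binomial(2, p_pop[labels, :]).astype(np.int8)
    if config.missing_rate > 0:
        geno[rng.random(size=geno.shape) < config.missing_rate] = MISSING

    # SNPs laid out over autosomes 1..22 with increasing positions
    chroms = np.array([(j % 22) + 1 for j in range(m)])
    order = np.argsort(chroms, kind="stable")
    chroms = chroms[order]
    geno = geno[:, order]
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        pos[idx] = 10_000 + 5_000 * np.arange(len(idx))
    meta = pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(m)],
            "chrom": [str(c) for c in chroms],
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    matrix = GenotypeMatrix(geno, meta, [f"ind{i:04d}" for i in range(n)])
    pop_labels = [f"pop{k}" for k in labels]
    return matrix, pop_labels


def hudson_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> np.ndarray:
    """Per-SNP Hudson F_ST from two populations' additive genotypes.

    Hudson's estimator: N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1), with allele-sample sizes n = 2 x individuals.
    Missing entries (-1) are excluded.  Used as the simulation's independent
    check that the realised differentiation matches ``fst_target``.
    """
    def _freq(g):
        ok = g != MISSING
        n_allele = 2.0 * ok.sum(axis=0)
        alt = np.where(ok, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return alt / n_allele, n_allele
    p1, n1 = _freq(geno_a)
    p2, n2 = _freq(geno_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return np.where(den > 0, num / den, np.nan)


def hudson_fst_genomewide(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Genome-wide Hudson F_ST as the ratio of averages.

    Summing numerator and denominator over SNPs before dividing avoids the
    downward Jensen bias of averaging per-SNP ratios and is the recommended
    multi-locus combination for Hudson's estimator.
    """
    def _freq(g):
        ok = g != MISSING
        n_allele = 2.0 * ok.sum(axis=0)
        alt = np.where(ok, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return alt / n_allele, n_allele

    p1, n1 = _freq(geno_a)
    p2, n2 = _freq(geno_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den)
    return float(num[ok].sum() / den[ok].sum())


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(population_labels, config: SimulationConfig) -> pd.DataFrame:
    """Covariate roster: sex, age, collection site, center, sequence count.

    With ``confound_strength`` c > 0, each individual's sequencing center is
    set to its population's designated center with probability c (uniform
    otherwise), so at c = 1 center deterministically tracks population.
    """
    rng = config.rng("covariates")
    labels = list(population_labels)
    n = len(labels)
    pops = sorted(set(labels))
    pop_idx = np.array([pops.index(l) for l in labels])

    sex = rng.integers(0, 2, size=n)
    age = np.round(rng.uniform(18, 40, size=n), 1)
    site = rng.choice(_SITES, size=n)
    center = rng.choice(_CENTERS, size=n)
    if config.confound_strength > 0:
        assigned = np.array([_CENTERS[k % len(_CENTERS)] for k in pop_idx])
        take = rng.random(n) < config.confound_strength
        center = np.where(take, assigned, center)
    total_seq = rng.lognormal(mean=16.0, sigma=0.5, size=n).astype(int) + 1

    return pd.DataFrame(
        {
            "individual": [f"ind{i:04d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "collection_site": site,
            "center": center,
            "total_sequences": total_seq,
        }
    ).set_index("individual")


# ---------------------------------------------------------------------------
# abundances

# fixed per-center log-abundance offsets (residual-SD units) applied to every
# taxon; these make sequencing center a genuine confounder whenever center
# correlates with population
_CENTER_EFFECT = {"BCM": 0.0, "BI": 0.5, "JCVI": -0.5, "WUGC": 1.0}


def simulate_abundances(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    body_site: str = "site01",
    rng: np.random.Generator | None = None,
):
    """Compositional taxon abundances with planted SNP effects.

    Log-abundance of taxon t in individual i is

        baseline_t + sum over causal pairs (t, s) of effect * g_is
                   + center_offset + 0.2 * sex + 0.01 * (age - 29)
                   + Normal(0, 1)

    then exponentiated and closed to relative abundance per sample (or drawn
    multinomially at ``count_depth`` reads when counts are requested).
    Missing causal genotypes contribute the SNP's observed mean, so
    complete-case regression downstream remains unbiased.  A causal SNP with
    zero variance among observed calls triggers a warning and is resampled.

    Returns ``(abundance DataFrame samples x taxa, taxonomy Series,
    GroundTruth)``.
    """
    if genotypes.n_snps == 0 or genotypes.n_individuals == 0:
        raise ValueError("genotype matrix must be non-empty")
    if rng is None:
        rng = config.rng("abundances")
    n, k = genotypes.n_individuals, config.n_taxa

    taxa = [f"taxon{t:03d}" for t in range(k)]
    genera = [
        f"k__Bacteria;p__P{t % 5};c__C{t % 7};o__O{t % 9};f__F{t % 11};g__G{t:03d}"
        for t in range(k)
    ]
    taxonomy = pd.Series(genera, index=taxa, name="lineage")

    # pick causal SNPs with non-zero variance among observed genotypes
    snp_ids = genotypes.snp_meta["id"].to_numpy()
    candidates = rng.permutation(genotypes.n_snps)
    causal_snps: list[int] = []
    # two passes: prefer SNPs that survive the default downstream QC
    # (observed MAF > 0.1, exact-HWE P > 1e-3) so planted ground truth stays
    # in the analysis set; fall back to any variable SNP if needed
    for strict in (True, False):
        for j in candidates:
            if len(causal_snps) == config.n_causal_pairs:
                break
            if j in causal_snps:
                continue
            col = genotypes.values[:, j]
            obs = col[col != MISSING]
            if len(obs) == 0 or obs.var() == 0:
                if not strict:
                    warnings.warn(
                        f"causal SNP {snp_ids[j]} has zero variance; resampling",
                        stacklevel=2,
                    )
                continue
            if strict:
                p = obs.sum() / (2.0 * len(obs))
                if min(p, 1 - p) <= 0.1:
                    continue
                hwe_p = hwe_exact_test(int((obs == 0).sum()),
                                       int((obs == 1).sum()),
                                       int((obs == 2).sum()))
                if hwe_p <= 1e-3:
                    continue
            causal_snps.append(int(j))
        if len(causal_snps) == config.n_causal_pairs:
            break
    if len(causal_snps) < config.n_causal_pairs:
        raise ValueError("not enough variable SNPs to place the causal pairs")
    causal_taxa = rng.choice(k, size=config.n_causal_pairs, replace=False)

    baseline = rng.normal(0.0, 2.0, size=k)
    log_ab = np.tile(baseline, (n, 1)) + rng.normal(0.0, 1.0, size=(n, k))

    truth = GroundTruth()
    for j, t in zip(causal_snps, causal_taxa):
        col = genotypes.values[:, j].astype(float)
        obs = col != MISSING
        g = np.where(obs, col, col[obs].mean())
        log_ab[:, t] += config.effect_size * g
        truth.causal_map.append((str(snp_ids[j]), taxa[int(t)], config.effect_size))

    if covariates is not None:
        cov = covariates.loc[list(genotypes.individual_ids)]
        offset = (
            cov["center"].map(_CENTER_EFFECT).to_numpy()
            + 0.2 * cov["sex"].to_numpy()
            + 0.01 * (cov["age"].to_numpy() - 29.0)
        )
        log_ab += offset[:, None]

    raw = np.exp(log_ab)
    rel = raw / raw.sum(axis=1, keepdims=True)
    if config.count_depth is not None:
        counts = np.vstack(
            [rng.multinomial(config.count_depth, rel[i]) for i in range(n)]
        )
        table = pd.DataFrame(counts, index=list(genotypes.individual_ids), columns=taxa)
    else:
        table = pd.DataFrame(rel, index=list(genotypes.individual_ids), columns=taxa)
    table.index.name = "sample"
    table.attrs["body_site"] = body_site
    return table, taxonomy, truth


# ---------------------------------------------------------------------------
# F_ST scores

# right-skewed background typical of genome-wide F_ST score distributions:
# most SNPs near zero, a long upper tail
_FST_BG = (0.6, 8.0)  # Beta shape parameters


def simulate_fst_scores(
    snp_ids,
    linked_ids=(),
    shift: float = 0.0,
    population_pairs=("AFR-vs-EUR",),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SNP F_ST scores with an optional median shift for linked SNPs.

    Background scores are drawn from a fixed right-skewed Beta distribution;
    SNPs in ``linked_ids`` receive ``+ shift`` (clipped to [0, 1]), which
    shifts their median by the same amount before clipping.  One independent
    draw per population pair.
    """
    snp_ids = list(snp_ids)
    linked = set(linked_ids)
    if not linked <= set(snp_ids):
        raise ValueError("linked_ids must be a subset of snp_ids")
    rng = np.random.default_rng(seed)
    frames = []
    is_linked = np.array([s in linked for s in snp_ids])
    for pair in population_pairs:
        fst = rng.beta(*_FST_BG, size=len(snp_ids))
        fst = np.clip(fst + shift * is_linked, 0.0, 1.0)
        frames.append(
            pd.DataFrame({"snp_id": snp_ids, "population_pair": pair, "fst": fst})
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# gene annotation


def make_gene_annotation(
    n_genes: int,
    chrom_lengths: dict,
    seed: int = 0,
    length_range: tuple = (2_000, 50_000),
) -> pd.DataFrame:
    """Random non-overlapping gene intervals (BED semantics).

    Genes are apportioned to chromosomes proportionally to length, given
    random lengths drawn from ``length_range``, and placed by distributing
    the leftover space as random gaps — guaranteeing sorted,
    non-overlapping, in-bounds half-open intervals.  Raises if the
    requested genes cannot fit.
    """
    rng = np.random.default_rng(seed)
    len_lo, len_hi = length_range
    chroms = list(chrom_lengths)
    if n_genes == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    total = sum(chrom_lengths.values())
    per = {c: int(round(n_genes * chrom_lengths[c] / total)) for c in chroms}
    # fix rounding drift
    drift = n_genes - sum(per.values())
    per[chroms[0]] += drift

    rows = []
    gi = 0
    for c in chroms:
        k = per[c]
        if k <= 0:
            continue
        length = chrom_lengths[c]
        lens = rng.integers(len_lo, len_hi, size=k)
        free = length - int(lens.sum())
        if free < 0:
            raise ValueError(
                f"cannot pack {k} genes of total length {int(lens.sum())} "
                f"into chromosome {c} of length {length}"
            )
        gaps = np.sort(rng.integers(0, free + 1, size=k))
        starts = gaps + np.concatenate([[0], np.cumsum(lens[:-1])])
        for s, l in zip(starts, lens):
            rows.append((str(c), int(s), int(s + l), f"gene{gi:05d}"))
            gi += 1
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(config: SimulationConfig, fst_shift: float = 0.0):
    """Generate every coupled piece of a study in memory.

    Returns a dict with keys ``genotypes``, ``population_labels``,
    ``covariates``, ``abundances`` (body_site -> DataFrame), ``taxonomy``,
    ``truth`` (body_site -> GroundTruth), ``fst_scores``, ``genes``.

    The causal SNP->taxon pairs are planted in the first body site only; the
    remaining sites are null, which is the structure the downstream
    false-positive checks rely on.  ``fst_shift`` raises the F_ST scores of
    the causal SNPs.
    """
    geno, pops = simulate_genotypes(config)
    cov = simulate_covariates(pops, config)

    ab_rng = config.rng("abundances")
    abundances, truths = {}, {}
    taxonomy = None
    for s in range(config.n_body_sites):
        site = f"site{s + 1:02d}"
        site_cfg = config if s == 0 else _null_config(config)
        table, taxonomy, truth = simulate_abundances(
            geno, site_cfg, covariates=cov, body_site=site, rng=ab_rng
        )
        abundances[site] = table
        truths[site] = truth

    linked = [snp for t in truths.values() for (snp, _, _) in t.causal_map]
    fst_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    fst_scores = simulate_fst_scores(
        geno.snp_meta["id"], linked, shift=fst_shift, seed=fst_seed
    )
    for t in truths.values():
        t.fst_shift = fst_shift
        t.population_labels = pops

    chrom_lengths = {
        str(c): int(geno.snp_meta.loc[geno.snp_meta["chrom"] == str(c), "pos"].max())
        + 50_000
        for c in sorted({int(x) for x in geno.snp_meta["chrom"]})
    }
    n_genes = max(10, config.n_snps // 5)
    # size genes to the simulated chromosome span so the packing always fits
    total_len = sum(chrom_lengths.values())
    hi = int(max(3_000, min(50_000, 0.4 * total_len / n_genes)))
    genes = make_gene_annotation(
        n_genes=n_genes,
        chrom_lengths=chrom_lengths,
        seed=fst_seed ^ 0x5F5F,
        length_range=(max(500, hi // 5), hi),
    )
    return {
        "genotypes": geno,
        "population_labels": pops,
        "covariates": cov,
        "abundances": abundances,
        "taxonomy": taxonomy,
        "truth": truths,
        "fst_scores": fst_scores,
        "genes": genes,
    }


def _null_config(config: SimulationConfig) -> SimulationConfig:
    d = asdict(config)
    d["n_causal_pairs"] = 0
    d["maf_range"] = tuple(d["maf_range"])
    return SimulationConfig(**d)
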