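"""Synthetic-data generator: determinism, calibration, and ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microgwas import (
    SimulationConfig,
    hudson_fst,
    make_gene_annotation,
    simulate_abundances,
    simulate_covariates,
    simulate_dataset,
    simulate_fst_scores,
    simulate_genotypes,
)


def _split_pops(geno, pops):
    lab = np.asarray(pops)
    a = geno.values[lab == "pop0"]
    b = geno.values[lab == "pop1"]
    return a, b


class TestGenotypes:
    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(fst_target=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(missing_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_snps=3, n_taxa=3, n_causal_pairs=4)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.4, 0.2))

    def test_zero_fst_means_no_differentiation(self):
        cfg = SimulationConfig(
            n_individuals=200, n_snps=5000, fst_target=0.0, missing_rate=0.0,
            n_causal_pairs=0, n_taxa=2, seed=1,
        )
        geno, pops = simulate_genotypes(cfg)
        fst = hudson_fst(*_split_pops(geno, pops))
        assert abs(np.nanmean(fst)) < 0.01

    def test_target_fst_recovered(self):
        from microgwas import hudson_fst_genomewide

        cfg = SimulationConfig(
            n_individuals=200, n_snps=5000, fst_target=0.1, missing_rate=0.0,
            n_causal_pairs=0, n_taxa=2, seed=2,
        )
        geno, pops = simulate_genotypes(cfg)
        # genome-wide (ratio-of-averages) estimate hits the target...
        assert hudson_fst_genomewide(*_split_pops(geno, pops)) == \
            pytest.approx(0.1, abs=0.02)
        # ...and the per-SNP mean lands in the same band despite its
        # ratio-averaging bias
        fst = hudson_fst(*_split_pops(geno, pops))
        assert np.nanmean(fst) == pytest.approx(0.1, abs=0.02)

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=5, n_snps=100, n_individuals=30, n_taxa=5,
                               n_causal_pairs=1)
        a, _ = simulate_genotypes(cfg)
        b, _ = simulate_genotypes(cfg)
        assert np.array_equal(a.values, b.values)
        assert a.snp_meta.equals(b.snp_meta)

    def test_missingness_rate_applied(self):
        cfg = SimulationConfig(n_individuals=300, n_snps=300, missing_rate=0.1,
                               n_taxa=2, n_causal_pairs=0, seed=3)
        geno, _ = simulate_genotypes(cfg)
        assert geno.missing_mask().mean() == pytest.approx(0.1, abs=0.01)

    def test_positions_valid_and_sorted(self):
        cfg = SimulationConfig(n_snps=100, n_individuals=10, n_taxa=2,
                               n_causal_pairs=0, seed=4)
        geno, _ = simulate_genotypes(cfg)
        for _, sub in geno.snp_meta.groupby("chrom"):
            assert (np.diff(sub["pos"]) > 0).all()


class TestAbundances:
    def test_closure(self):
        cfg = SimulationConfig(n_individuals=1, n_snps=10, n_taxa=7,
                               n_causal_pairs=0, missing_rate=0.0, seed=6)
        geno, _ = simulate_genotypes(cfg)
        table, _, _ = simulate_abundances(geno, cfg)
        assert table.to_numpy().sum(axis=1) == pytest.approx(1.0, abs=1e-9)

    def test_count_mode_depth(self):
        cfg = SimulationConfig(n_individuals=5, n_snps=10, n_taxa=7,
                               n_causal_pairs=0, count_depth=1000, seed=6)
        geno, _ = simulate_genotypes(cfg)
        table, _, _ = simulate_abundances(geno, cfg)
        assert (table.sum(axis=1) == 1000).all()

    def test_null_effect_p_uniform(self):
        """With effect 0, the causal-SNP regression P is Uniform(0,1)."""
        pvals = []
        for rep in range(500):
            rng = np.random.default_rng(1000 + rep)
            g = rng.binomial(2, 0.3, size=60)
            cfg = SimulationConfig(n_individuals=60, n_snps=5, n_taxa=10,
                                   n_causal_pairs=1, effect_size=0.0,
                                   missing_rate=0.0, seed=1000 + rep)
            geno, _ = simulate_genotypes(cfg)
            table, _, truth = simulate_abundances(geno, cfg)
            snp, taxon, _ = truth.causal_map[0]
            j = list(geno.snp_meta["id"]).index(snp)
            y = np.log(table[taxon].to_numpy())
            res = stats.linregress(geno.values[:, j].astype(float), y)
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_effect_size_recovered(self):
        """OLS slope of log-abundance on the causal SNP ~ effect size."""
        slopes = []
        for rep in range(100):
            cfg = SimulationConfig(n_individuals=500, n_snps=30, n_taxa=50,
                                   n_causal_pairs=1, effect_size=1.0,
                                   missing_rate=0.0, seed=2000 + rep)
            geno, _ = simulate_genotypes(cfg)
            table, _, truth = simulate_abundances(geno, cfg)
            snp, taxon, _ = truth.causal_map[0]
            j = list(geno.snp_meta["id"]).index(snp)
            y = np.log(table[taxon].to_numpy())
            slopes.append(
                stats.linregress(geno.values[:, j].astype(float), y).slope
            )
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.15)

    def test_noncausal_taxa_independent_of_genotype(self):
        cfg = SimulationConfig(n_individuals=400, n_snps=10, n_taxa=10,
                               n_causal_pairs=1, effect_size=2.0,
                               missing_rate=0.0, seed=8)
        geno, _ = simulate_genotypes(cfg)
        table, _, truth = simulate_abundances(geno, cfg)
        snp, causal_taxon, _ = truth.causal_map[0]
        j = list(geno.snp_meta["id"]).index(snp)
        g = geno.values[:, j].astype(float)
        others = [t for t in table.columns if t != causal_taxon]
        # closure induces only a weak anti-correlation; nothing should look
        # like the planted effect
        r_causal = abs(stats.pearsonr(g, np.log(table[causal_taxon]))[0])
        r_others = max(abs(stats.pearsonr(g, np.log(table[t]))[0]) for t in others)
        assert r_causal > r_others

    def test_empty_genotypes_rejected(self):
        cfg = SimulationConfig(n_taxa=5, n_causal_pairs=0)
        geno, _ = simulate_genotypes(SimulationConfig(n_individuals=2, n_snps=1,
                                                      n_taxa=5, n_causal_pairs=0))
        empty = geno.take_snps([])
        with pytest.raises(ValueError):
            simulate_abundances(empty, cfg)


class TestCovariates:
    @staticmethod
    def _cramers_v(a, b):
        tab = pd.crosstab(pd.Series(np.asarray(a)), pd.Series(np.asarray(b))).to_numpy()
        chi2 = stats.chi2_contingency(tab, correction=False)[0]
        n = tab.sum()
        k = min(tab.shape) - 1
        return np.sqrt(chi2 / (n * k))

    def test_no_confounding_by_default(self):
        cfg = SimulationConfig(n_individuals=500, n_snps=10, n_taxa=2,
                               n_causal_pairs=0, confound_strength=0.0, seed=9)
        _, pops = simulate_genotypes(cfg)
        cov = simulate_covariates(pops, cfg)
        assert self._cramers_v(cov["center"], pops) < 0.1

    def test_full_confounding_is_deterministic(self):
        cfg = SimulationConfig(n_individuals=100, n_snps=10, n_taxa=2,
                               n_causal_pairs=0, confound_strength=1.0, seed=10)
        _, pops = simulate_genotypes(cfg)
        cov = simulate_covariates(pops, cfg)
        mapping = {"pop0": "BCM", "pop1": "BI", "pop2": "JCVI", "pop3": "WUGC"}
        assert (cov["center"].to_numpy() ==
                np.array([mapping[p] for p in pops])).all()

    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_individuals=50, n_snps=10, n_taxa=2,
                               n_causal_pairs=0, seed=11)
        _, pops = simulate_genotypes(cfg)
        assert simulate_covariates(pops, cfg).equals(simulate_covariates(pops, cfg))


class TestFstScores:
    def test_empty_linked_set_is_background(self):
        a = simulate_fst_scores([f"s{i}" for i in range(100)], [], shift=0.5, seed=1)
        b = simulate_fst_scores([f"s{i}" for i in range(100)], [], shift=0.0, seed=1)
        assert np.allclose(a["fst"], b["fst"])

    def test_shift_moves_linked_median(self):
        ids = [f"s{i}" for i in range(2000)]
        linked = ids[:500]
        df = simulate_fst_scores(ids, linked, shift=0.2, seed=2)
        med_linked = df[df["snp_id"].isin(linked)]["fst"].median()
        med_bg = df[~df["snp_id"].isin(linked)]["fst"].median()
        assert med_linked - med_bg == pytest.approx(0.2, abs=0.03)

    def test_linked_must_be_subset(self):
        with pytest.raises(ValueError):
            simulate_fst_scores(["a"], ["b"], 0.1)

    def test_scores_in_unit_interval(self):
        df = simulate_fst_scores([f"s{i}" for i in range(100)],
                                 [f"s{i}" for i in range(50)], shift=0.9, seed=3)
        assert df["fst"].between(0, 1).all()


class TestGeneAnnotation:
    def test_intervals_valid_sorted_unique(self):
        genes = make_gene_annotation(50, {"1": 2_000_000, "2": 3_000_000}, seed=1)
        assert len(genes) == 50
        assert genes["name"].is_unique
        for chrom, sub in genes.groupby("chrom"):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            assert (s < e).all()
            assert (s[1:] >= e[:-1]).all()  # non-overlapping
            assert e.max() <= {"1": 2_000_000, "2": 3_000_000}[chrom]

    def test_identical_seed_identical_output(self):
        a = make_gene_annotation(20, {"1": 5_000_000}, seed=7)
        b = make_gene_annotation(20, {"1": 5_000_000}, seed=7)
        assert a.equals(b)

    def test_zero_genes(self):
        assert make_gene_annotation(0, {"1": 1000}, seed=1).empty

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            make_gene_annotation(100, {"1": 10_000}, seed=1)


class TestDataset:
    def test_deterministic_and_coherent(self):
        cfg = SimulationConfig(n_individuals=30, n_snps=60, n_taxa=10,
                               n_causal_pairs=2, n_body_sites=2, seed=12)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert np.array_equal(a["genotypes"].values, b["genotypes"].values)
        assert a["covariates"].equals(b["covariates"])
        for s in a["abundances"]:
            assert a["abundances"][s].equals(b["abundances"][s])
        assert np.allclose(a["fst_scores"]["fst"], b["fst_scores"]["fst"])
        # ground truth refers to emitted objects only
        snp_ids = set(a["genotypes"].snp_meta["id"])
        for site, truth in a["truth"].items():
            for snp, taxon, _ in truth.causal_map:
                assert snp in snp_ids
                assert taxon in a["abundances"][site].columns

    def test_causal_pairs_only_in_first_site(self):
        cfg = SimulationConfig(n_individuals=30, n_snps=60, n_taxa=10,
                               n_causal_pairs=2, n_body_sites=3, seed=13)
        data = simulate_dataset(cfg)
        sites = sorted(data["truth"])
        assert len(data["truth"][sites[0]].causal_map) == 2
        assert all(not data["truth"][s].causal_map for s in sites[1:])
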