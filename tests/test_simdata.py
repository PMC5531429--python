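"""Generative-model checks for the synthetic cohort simulator."""

import numpy as np
import pytest

from paleoweave import simdata
from paleoweave.simdata import (
    AccuracySchedule,
    AdmixtureEvent,
    ConfigurationError,
    SimConfig,
    SourceSpec,
    TraitConfig,
    emulate_imputed_calls,
    simulate_admixed,
    simulate_reads,
    simulate_sources,
    simulate_trait,
    tract_fraction_by_rescan,
)
from paleoweave import calls

from helpers import two_source_config

# Monte-Carlo oracle of the two-population Balding-Nichols model (F = 0.1
# each side, p ~ U(0.05, 0.95)): Hudson-type FST as a ratio of averages,
# computed from 2e6 draws of the stated generative model before the
# simulator was written.
HUDSON_FST_ORACLE_F01 = 0.100


def _hudson_fst(h1, h2):
    """Sample-corrected Hudson FST from two haplotype matrices."""
    n1, n2 = h1.shape[0], h2.shape[0]
    p1 = h1.mean(axis=0)
    p2 = h2.mean(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return num[keep].sum() / den[keep].sum()


class TestSources:
    def test_near_zero_drift_leaves_populations_undifferentiated(self):
        cfg = two_source_config(seed=3, n_sites=5000, F=1e-6, n_founders=200, n_samples=20)
        panel = simulate_sources(cfg)
        fst = _hudson_fst(panel.haplotypes["A"], panel.haplotypes["B"])
        assert abs(fst) < 0.01

    def test_hudson_fst_matches_generative_model_oracle(self):
        cfg = two_source_config(seed=5, n_sites=5000, F=0.1, n_founders=100, n_samples=25)
        panel = simulate_sources(cfg)
        fst = _hudson_fst(panel.haplotypes["A"], panel.haplotypes["B"])
        assert fst == pytest.approx(HUDSON_FST_ORACLE_F01, abs=0.03)

    def test_same_seed_reproduces_panel_exactly(self):
        cfg = two_source_config(seed=9, n_sites=600)
        p1 = simulate_sources(cfg)
        p2 = simulate_sources(two_source_config(seed=9, n_sites=600))
        assert p1.sites.equals(p2.sites)
        for pop in p1.haplotypes:
            assert np.array_equal(p1.haplotypes[pop], p2.haplotypes[pop])

    def test_positions_strictly_increasing_and_alleles_valid(self, two_source_panel):
        _, panel = two_source_panel
        pos = panel.sites["position_bp"].to_numpy()
        assert np.all(np.diff(pos) > 0)
        assert not np.any(panel.sites["ref_allele"] == panel.sites["alt_allele"])
        ti = panel.sites["mutation_class"] == "transition"
        pairs = {frozenset(p) for p in zip(panel.sites.loc[ti, "ref_allele"],
                                           panel.sites.loc[ti, "alt_allele"])}
        assert pairs <= {frozenset("AG"), frozenset("CT")}

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            two_source_config(F=1.5).validate()
        with pytest.raises(ConfigurationError):
            cfg = two_source_config()
            cfg.coverage_lambda = -1
            cfg.validate()
        with pytest.raises(ConfigurationError):
            cfg = SimConfig(sources=[SourceSpec("A", 0.1, 5, 5), SourceSpec("A", 0.1, 5, 5)])
            cfg.validate()


class TestAdmixture:
    def test_alpha_one_yields_pure_source_a(self, two_source_panel):
        cfg, panel = two_source_panel
        simulate_admixed(panel, AdmixtureEvent("pureA", "A", "B", 1.0, 20, 5), cfg.seed)
        frac = panel.truth_ancestry_fraction("pureA", "A")
        assert np.all(frac == 1.0)

    def test_mean_ancestry_fraction_near_alpha(self):
        cfg = two_source_config(seed=21, n_sites=400)
        panel = simulate_sources(cfg)
        simulate_admixed(panel, AdmixtureEvent("X", "A", "B", 0.25, 30, 25), cfg.seed)
        frac = panel.truth_ancestry_fraction("X", "A")
        assert abs(frac.mean() - 0.25) < 0.05

    def test_doubling_switch_intensity_doubles_tract_count(self):
        counts = {}
        for g in (15, 30):
            cfg = two_source_config(seed=33, n_sites=300)
            panel = simulate_sources(cfg)
            simulate_admixed(panel, AdmixtureEvent("X", "A", "B", 0.25, g, 100), cfg.seed + g)
            counts[g] = np.mean([len(t) for t in panel.truth_tracts["X"]])
        # merged-tract counts are 1 + (effective switches); compare the
        # Poisson-driven excess over the single-tract baseline
        ratio = (counts[30] - 1) / (counts[15] - 1)
        assert 1.7 < ratio < 2.3

    def test_tract_bookkeeping_matches_rescan_exactly(self, admixed_panel):
        _, panel = admixed_panel
        direct = panel.truth_ancestry_fraction("X", "A")
        rescan = tract_fraction_by_rescan(panel, "X", "A")
        assert np.array_equal(direct, rescan)

    def test_unknown_source_rejected(self, two_source_panel):
        cfg, panel = two_source_panel
        with pytest.raises(ConfigurationError):
            simulate_admixed(panel, AdmixtureEvent("Y", "A", "nope", 0.5, 10, 2), cfg.seed)


class TestReads:
    def test_error_free_reads_match_true_chromosome(self, two_source_panel):
        cfg, panel = two_source_panel
        clean = two_source_config(seed=cfg.seed, n_sites=cfg.n_sites,
                                  deamination_delta=0.0, seq_error_eps=0.0)
        pile = simulate_reads(panel, [("A", 0), ("A", 1)], clean)
        assert np.array_equal(pile.observed, pile.true_allele)
        assert not pile.damage_flag.any()

    def test_terminal_deamination_rate_matches_delta(self):
        # panel where every site is C/T with all-ref (susceptible) haplotypes
        import pandas as pd

        n_sites = 4000
        sites = pd.DataFrame(
            {
                "position_bp": np.arange(n_sites) * 1000,
                "genetic_pos_cM": np.linspace(0, 100, n_sites),
                "ref_allele": "C",
                "alt_allele": "T",
                "mutation_class": "transition",
            }
        )
        panel = simdata.HaplotypePanel(
            sites=sites,
            haplotypes={"P": np.zeros((2, n_sites), dtype=np.uint8)},
            chrom_length_bp=n_sites * 1000,
            map_length_cM=100.0,
        )
        cfg = SimConfig(n_sites=n_sites, chrom_length_bp=n_sites * 1000,
                        sources=[SourceSpec("P", 0.1, 2, 1)],
                        coverage_lambda=50, deamination_delta=0.3,
                        seq_error_eps=0.0, seed=17)
        pile = simulate_reads(panel, [("P", 0)], cfg)
        terminal = pile.dist5 == 0
        n = terminal.sum()
        rate = pile.observed[terminal].mean()  # all reads eligible, flip -> alt
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(rate - 0.3) < 3 * sd

    def test_poisson_zero_class_at_low_coverage(self, two_source_panel):
        cfg, panel = two_source_panel
        low = two_source_config(seed=2, n_sites=cfg.n_sites, coverage_lambda=0.1)
        inds = [("A", i) for i in range(8)] + [("B", i) for i in range(8)]
        pile = simulate_reads(panel, inds, low)
        covered = len(set(zip(pile.ind_idx.tolist(), pile.site_idx.tolist())))
        frac = covered / (16 * cfg.n_sites)
        assert abs(frac - (1 - np.exp(-0.1))) < 0.01


class TestImputedCalls:
    def test_perfect_accuracy_is_identity_with_consistent_gp(self, two_source_panel):
        _, panel = two_source_panel
        truth = calls.from_panel(panel, ["A"])
        out = emulate_imputed_calls(truth, AccuracySchedule.constant(1, 1, 1), seed=4)
        assert np.array_equal(out.values, truth.values)
        assert np.array_equal(np.argmax(out.gp, axis=2), out.values)

    def test_het_concordance_matches_configured_accuracy(self):
        cfg = two_source_config(seed=41, n_sites=4000, n_samples=20)
        panel = simulate_sources(cfg)
        truth = calls.from_panel(panel, ["A", "B"])
        out = emulate_imputed_calls(truth, AccuracySchedule.constant(1.0, 0.95, 1.0), seed=8)
        het = truth.values == 1
        n = het.sum()
        assert n > 10_000
        conc = (out.values[het] == 1).mean()
        sd = np.sqrt(0.95 * 0.05 / n)
        assert abs(conc - 0.95) < 3 * sd

    def test_accuracy_rising_in_maf_measured_as_nondecreasing(self):
        cfg = two_source_config(seed=43, n_sites=6000, n_samples=25)
        panel = simulate_sources(cfg)
        truth = calls.from_panel(panel, ["A", "B"])
        n_bins = 100
        rising = np.linspace(0.7, 1.0, n_bins)[:, None].repeat(3, axis=1)
        out = emulate_imputed_calls(truth, AccuracySchedule(0.005, rising), seed=9)
        acc = calls.imputation_accuracy(truth, out, bin_width=0.05)
        pooled = acc.table.groupby("maf_bin").apply(
            lambda t: t["n_concordant"].sum() / t["n_compared"].sum(), include_groups=False
        )
        # coarse re-binning smooths noise; demand a clear upward trend
        assert pooled.iloc[-1] > pooled.iloc[0]
        assert np.polyfit(range(len(pooled)), pooled.to_numpy(), 1)[0] > 0


class TestTrait:
    def test_zero_causal_sites_gives_zero_values(self, two_source_panel):
        _, panel = two_source_panel
        _, truth = simulate_trait(panel, TraitConfig(n_causal=0), seed=1)
        assert np.all(truth["true_value"] == 0)

    def test_score_on_truth_genotypes_recovers_true_value(self, two_source_panel):
        from paleoweave import traits

        _, panel = two_source_panel
        epanel, truth = simulate_trait(panel, TraitConfig(n_causal=100), seed=2)
        mat = calls.from_panel(panel, ["A", "B"])
        res = traits.polygenic_score(mat, epanel, p_threshold=1e-6)
        merged = truth.set_index("individual").loc[res.scores.index]
        r = np.corrcoef(res.scores.to_numpy(), merged["true_value"].to_numpy())[0, 1]
        assert r > 0.99

    def test_frequency_offset_drives_score_difference_sign(self):
        # strongly diverged pops: mean score difference matches sum beta * 2 dq
        cfg = two_source_config(seed=55, n_sites=2000, F=0.3, n_samples=20)
        panel = simulate_sources(cfg)
        epanel, truth = simulate_trait(panel, TraitConfig(n_causal=150), seed=3)
        by_pop = truth.groupby("population")["true_value"].mean()
        causal = epanel.table[epanel.table["p_value"] < 1e-6]
        beta = causal["beta"].to_numpy()
        qa = panel.haplotypes["A"].mean(axis=0)[causal["site_idx"]]
        qb = panel.haplotypes["B"].mean(axis=0)[causal["site_idx"]]
        expected = float(np.sum(beta * 2 * (qa - qb)))
        assert np.sign(by_pop["A"] - by_pop["B"]) == np.sign(expected)
        assert by_pop["A"] - by_pop["B"] == pytest.approx(expected, abs=1e-9)
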