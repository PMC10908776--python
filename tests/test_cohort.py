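"""Synthetic-cohort generator: genotype structure, weights, outcomes, trials."""

import numpy as np
import pandas as pd
import pytest

from psygrs import (
    SimulationConfig,
    TreatmentRecord,
    compute_grs,
    count_adequate_trials,
    derive_endpoints,
    harmonize_weights,
    hwe_chisq,
    simulate_genotypes,
    simulate_outcomes,
    simulate_weights,
)
from psygrs.cohort import _SAFE_PAIRS


def _flat_config(**kw):
    base = dict(ld_block_sizes=[], ld_within_block_r=0.0, n_weights_extra=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateGenotypes:
    def test_single_population_hwe_frequencies(self):
        """Genotype class frequencies match (1-p)^2, 2p(1-p), p^2 within 3 binomial SDs."""
        n = 10_000
        cfg = _flat_config(n_individuals=n, n_variants=30, seed=5)
        gm = simulate_genotypes(cfg)
        p = gm.alt_freq()
        for j in range(gm.n_variants):
            d = gm.dosages[:, j]
            expected = np.array([(1 - p[j]) ** 2, 2 * p[j] * (1 - p[j]), p[j] ** 2])
            observed = np.array([(d == 0).mean(), (d == 1).mean(), (d == 2).mean()])
            sd = np.sqrt(expected * (1 - expected) / n)
            assert (np.abs(observed - expected) < 3.5 * sd).all()

    def test_hwe_chi_square_pass_rate(self):
        """Single-population variants essentially never fail HWE at p > 1e-6."""
        cfg = _flat_config(n_individuals=10_000, n_variants=200, seed=6)
        gm = simulate_genotypes(cfg)
        pvals = np.array([hwe_chisq(gm.dosages[:, j])[1] for j in range(gm.n_variants)])
        assert (pvals > 1e-6).all()

    def test_ld_block_pair_correlation(self):
        """A latent block correlation of 0.99 yields empirical genotype r^2 > 0.9."""
        cfg = SimulationConfig(
            n_individuals=5000, n_variants=2, ld_block_sizes=[2], ld_within_block_r=0.99, seed=7,
            n_weights_extra=0,
        )
        gm = simulate_genotypes(cfg)
        r = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 1])[0, 1]
        assert r**2 > 0.9

    def test_independent_variants_uncorrelated(self):
        cfg = _flat_config(n_individuals=4000, n_variants=10, seed=8)
        gm = simulate_genotypes(cfg)
        r2 = np.corrcoef(gm.dosages.T) ** 2
        np.fill_diagonal(r2, 0)
        assert r2.max() < 0.1

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=42)
        a, b = simulate_genotypes(cfg), simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages, equal_nan=True)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_balding_nichols_subpopulation_divergence(self):
        """Higher Fst spreads subpopulation allele frequencies further apart."""
        spreads = []
        for fst in (0.01, 0.3):
            cfg = _flat_config(n_individuals=2000, n_variants=50, n_subpops=2, subpop_fst=fst, seed=9)
            gm = simulate_genotypes(cfg)
            f0 = gm.dosages[gm.subpop == 0].mean(axis=0) / 2
            f1 = gm.dosages[gm.subpop == 1].mean(axis=0) / 2
            spreads.append(np.abs(f0 - f1).mean())
        assert spreads[1] > spreads[0]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_individuals=0),
            dict(n_variants=-3),
            dict(maf_range=(0.0, 0.5)),
            dict(maf_range=(0.2, 0.6)),
            dict(ld_block_sizes=[100], n_variants=38),
            dict(ld_within_block_r=1.0),
            dict(trial_count_probs=(0.5, 0.4)),
            dict(dropout_rate=1.5),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSimulateWeights:
    def test_no_causal_variants_all_betas_zero(self):
        cfg = _flat_config(n_variants=20, n_causal=0, seed=3)
        gm = simulate_genotypes(cfg)
        w = simulate_weights(gm, cfg)
        assert (w["beta"] == 0).all()
        ws = harmonize_weights(w, gm)
        scores = compute_grs(gm, ws, mode="sum")
        assert np.allclose(scores.values, 0.0)

    def test_exactly_fourteen_nonzero_weights(self):
        """The study's GRS carried 14 independently weighted SNPs."""
        cfg = _flat_config(n_variants=38, n_causal=14, seed=3)
        gm = simulate_genotypes(cfg)
        w = simulate_weights(gm, cfg)
        assert (w["beta"] != 0).sum() == 14

    def test_all_p_values_below_suggestive_cut(self):
        cfg = SimulationConfig(seed=4)
        gm = simulate_genotypes(cfg)
        w = simulate_weights(gm, cfg)
        assert (w["p_value"] < 5.0e-6).all()

    def test_swapped_orientation_is_harmonized_away(self):
        """Emitting every record in flipped orientation leaves the GRS unchanged."""
        cfg = _flat_config(n_variants=20, seed=12)
        gm = simulate_genotypes(cfg)
        straight = simulate_weights(gm, SimulationConfig(**{**cfg.__dict__, "swap_allele_fraction": 0.0}))
        flipped = straight.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        s1 = compute_grs(gm, harmonize_weights(straight, gm), mode="sum").values
        s2 = compute_grs(gm, harmonize_weights(flipped, gm), mode="sum").values
        ws2 = harmonize_weights(flipped, gm)
        assert ws2.report["n_sign_flipped"] == ws2.report["n_matched"]
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_n_causal_exceeding_panel_rejected(self):
        with pytest.raises(ValueError):
            _flat_config(n_variants=10, n_causal=11)


class TestSimulateOutcomes:
    def test_null_grs_gives_null_correlation(self, rng):
        """With beta_grs=0 the GRS-response correlation is centred on zero."""
        rs = []
        for s in range(200):
            cfg = SimulationConfig(seed=s, n_individuals=500, beta_grs=0.0, dropout_rate=0.0)
            z = rng.normal(size=500)
            ph = simulate_outcomes(z, cfg)
            rs.append(np.corrcoef(z, ph["nonresponse"])[0, 1])
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.01

    def test_strong_grs_enriches_top_decile(self, rng):
        """At beta_grs=1.5 the top decile's event rate beats the cohort rate."""
        wins = 0
        for s in range(200):
            cfg = SimulationConfig(seed=s, n_individuals=500, beta_grs=1.5, dropout_rate=0.0)
            z = rng.normal(size=500)
            ph = simulate_outcomes(z, cfg)
            y = ph["nonresponse"].to_numpy()
            top = z >= np.quantile(z, 0.9)
            if y[top].mean() > y.mean():
                wins += 1
        assert wins > 0.95 * 200

    def test_dropout_expectation_matches_study(self):
        """dropout_rate=0.178 at n=107 masks ~19 week-7 scores on average."""
        counts = [
            simulate_outcomes(np.zeros(107), SimulationConfig(seed=s))["hamd_week7"].isna().sum()
            for s in range(60)
        ]
        assert abs(np.mean(counts) - 19.0) < 1.6

    def test_endpoints_consistent_with_trajectories(self, default_cohort):
        """Week-7 scores reproduce the drawn endpoint flags exactly."""
        _, _, ph = default_cohort
        nr, nm = derive_endpoints(ph["hamd_baseline"], ph["hamd_week7_complete"])
        np.testing.assert_array_equal(nr, ph["nonresponse_complete"])
        np.testing.assert_array_equal(nm, ph["nonremission_complete"])

    def test_remission_nested_in_response(self, default_cohort):
        """Every nonresponder is a nonremitter (remitters form a subset of responders)."""
        _, _, ph = default_cohort
        assert (ph["nonremission_complete"] >= ph["nonresponse_complete"]).all()

    def test_baseline_meets_inclusion_threshold(self, default_cohort):
        _, _, ph = default_cohort
        assert (ph["hamd_baseline"] >= 18).all()

    def test_trial_counts_follow_configured_probabilities(self):
        cfg = SimulationConfig(seed=13, n_individuals=5000)
        ph = simulate_outcomes(np.zeros(5000), cfg)
        frac0 = (ph["n_adequate_trials"] == 0).mean()
        assert abs(frac0 - 0.757) < 3 * np.sqrt(0.757 * 0.243 / 5000)

    def test_histories_reproduce_counts(self, default_cohort):
        _, _, ph = default_cohort
        for hist, k in zip(ph["treatment_history"], ph["n_adequate_trials"]):
            records = [TreatmentRecord(**r) for r in hist]
            assert count_adequate_trials(records) == k

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            simulate_outcomes(np.array([1.0, np.nan]), SimulationConfig(n_individuals=2))


class TestCountAdequateTrials:
    @pytest.mark.parametrize(
        "records,expected",
        [
            ([], 0),
            ([("ssri", True, 6.0, 3)], 1),
            ([("ssri", True, 4.0, 2), ("ssri", True, 3.9, 5), ("ssri", False, 10.0, 5)], 0),
            ([("ssri", True, 4.0, 3), ("tca", True, 8.0, 5), ("ssri", True, 2.0, 4)], 2),
        ],
    )
    def test_adequacy_rule(self, records, expected):
        history = [TreatmentRecord(*r) for r in records]
        assert count_adequate_trials(history) == expected

    def test_invalid_athf_score_rejected(self):
        with pytest.raises(ValueError):
            TreatmentRecord("ssri", True, 6.0, 6)
        with pytest.raises(ValueError):
            TreatmentRecord("ssri", True, -1.0, 3)
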