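"""GRS engine: variant QC, harmonization, LD pruning and scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psygrs import (
    GenotypeMatrix,
    SimulationConfig,
    compute_grs,
    harmonize_weights,
    hwe_chisq,
    prune_ld,
    qc_variants,
    simulate_genotypes,
    simulate_weights,
)
from psygrs.scoring import EmptyPanelError, WeightSet


def _panel(dosage_columns, refs=None, alts=None, chrom="1"):
    dosages = np.column_stack(dosage_columns).astype(float)
    m = dosages.shape[1]
    refs = refs or ["A"] * m
    alts = alts or ["G"] * m
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * 100,
            "ref": refs,
            "alt": alts,
        }
    )
    return GenotypeMatrix(samples=[f"s{i}" for i in range(dosages.shape[0])], variants=variants, dosages=dosages)


def _weights(ids, betas):
    return WeightSet(
        table=pd.DataFrame(
            {
                "variant_id": ids,
                "counted_allele": ["G"] * len(ids),
                "aligned_beta": betas,
                "sign_flipped": [False] * len(ids),
            }
        )
    )


class TestQC:
    def test_monomorphic_variant_removed(self):
        gm = _panel([np.zeros(100), np.tile([0, 1, 1, 2], 25)])
        out = qc_variants(gm)
        assert out.variants["variant_id"].tolist() == ["v1"]

    def test_exact_hwe_proportions_retained(self):
        d = np.repeat([0, 1, 2], [25, 50, 25])
        chi2, p = hwe_chisq(d)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        out = qc_variants(_panel([d, d]))
        assert out.n_variants == 2

    def test_extreme_heterozygote_deficit_removed(self):
        """No hets at p=0.5: chi-square is exactly 100 at n=100, far past 1e-6."""
        d = np.repeat([0, 2], [50, 50])
        chi2, p = hwe_chisq(d)
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-6
        keep = np.tile([0, 1, 1, 2], 25)
        out = qc_variants(_panel([d, keep]))
        assert out.variants["variant_id"].tolist() == ["v1"]

    def test_low_call_rate_removed(self):
        good = np.tile([0.0, 1.0, 1.0, 2.0], 25)
        bad = good.copy()
        bad[:5] = np.nan  # 95% call rate < 98%
        out = qc_variants(_panel([bad, good]))
        assert out.variants["variant_id"].tolist() == ["v1"]

    def test_empty_panel_raises_distinct_error(self):
        with pytest.raises(EmptyPanelError):
            qc_variants(_panel([np.zeros(50)]))

    def test_idempotent(self):
        cfg = SimulationConfig(seed=21, genotype_missing_rate=0.01)
        gm = simulate_genotypes(cfg)
        once = qc_variants(gm)
        twice = qc_variants(once)
        assert once.variants["variant_id"].tolist() == twice.variants["variant_id"].tolist()
        assert np.array_equal(once.dosages, twice.dosages, equal_nan=True)

    def test_threshold_domain_checked(self):
        gm = _panel([np.tile([0, 1, 1, 2], 25)])
        with pytest.raises(ValueError):
            qc_variants(gm, maf_min=0.0)


class TestHarmonize:
    def _stats(self, rows):
        return pd.DataFrame(
            rows, columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p_value"]
        )

    def test_identity_orientation_keeps_beta(self):
        gm = _panel([np.tile([0, 1, 2], 10)], refs=["A"], alts=["G"])
        ws = harmonize_weights(self._stats([("v0", "1", 100, "G", "A", 0.12, 1e-7)]), gm)
        assert ws.table.loc[0, "aligned_beta"] == 0.12
        assert not ws.table.loc[0, "sign_flipped"]

    def test_reverse_orientation_flips_sign(self):
        gm = _panel([np.tile([0, 1, 2], 10)], refs=["A"], alts=["G"])
        ws = harmonize_weights(self._stats([("v0", "1", 100, "A", "G", 0.12, 1e-7)]), gm)
        assert ws.table.loc[0, "aligned_beta"] == -0.12
        assert bool(ws.table.loc[0, "sign_flipped"])
        assert ws.report["n_sign_flipped"] == 1

    @pytest.mark.parametrize("ea,oa", [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")])
    def test_strand_ambiguous_dropped(self, ea, oa):
        gm = _panel([np.tile([0, 1, 2], 10)], refs=[oa], alts=[ea])
        ws = harmonize_weights(self._stats([("v0", "1", 100, ea, oa, 0.2, 1e-7)]), gm)
        assert len(ws) == 0
        assert ws.report["n_ambiguous"] == 1

    def test_unmatched_and_mismatched_counted(self):
        gm = _panel([np.tile([0, 1, 2], 10)], refs=["A"], alts=["G"])
        stats = self._stats(
            [
                ("v0", "1", 100, "C", "A", 0.1, 1e-7),  # alleles match neither orientation
                ("missing", "1", 200, "G", "A", 0.1, 1e-7),
                ("v0", "1", 100, "G", "A", 0.1, 0.5),  # fails the p filter
            ]
        )
        ws = harmonize_weights(stats, gm)
        assert len(ws) == 0
        assert ws.report["n_allele_mismatch"] == 1
        assert ws.report["n_unmatched_id"] == 1
        assert ws.report["n_p_excluded"] == 1

    def test_study_counts_52_to_38_to_14(self, default_cohort):
        """52 input records, 38 on the panel, 14 after LD pruning — the study trajectory."""
        gm, stats, _ = default_cohort
        gm_qc = qc_variants(gm)
        ws = harmonize_weights(stats, gm_qc)
        assert ws.report["n_input"] == 52
        assert ws.report["n_matched"] == 38
        pruned = prune_ld(gm_qc, ws)
        assert len(pruned) == 14


class TestPrune:
    def test_duplicated_variant_keeps_one(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        gm = _panel([d, d.copy()])
        ws = _weights(["v0", "v1"], [0.3, 0.1])
        out = prune_ld(gm, ws, window_variants=10, step_variants=5, r2_max=0.5)
        assert out.variant_ids == ["v0"]  # larger |beta| survives

    def test_tie_broken_by_larger_position(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        gm = _panel([d, d.copy()])
        ws = _weights(["v0", "v1"], [0.2, 0.2])
        out = prune_ld(gm, ws, window_variants=10, step_variants=5, r2_max=0.5)
        assert out.variant_ids == ["v0"]  # equal betas: larger pos removed

    def test_independent_variants_all_retained(self, rng):
        cols = [rng.integers(0, 3, size=500).astype(float) for _ in range(8)]
        gm = _panel(cols)
        ws = _weights([f"v{j}" for j in range(8)], rng.normal(size=8))
        out = prune_ld(gm, ws, window_variants=10, step_variants=5, r2_max=0.5)
        assert len(out) == 8

    def test_survivors_pass_exhaustive_scan(self, default_cohort):
        """Brute-force all-pairs r^2 on the survivor set stays at or below the threshold."""
        gm, stats, _ = default_cohort
        gm_qc = qc_variants(gm)
        pruned = prune_ld(gm_qc, harmonize_weights(stats, gm_qc))
        cols = np.column_stack([gm_qc.column(v) for v in pruned.variant_ids])
        r2 = np.corrcoef(cols.T) ** 2
        np.fill_diagonal(r2, 0.0)
        assert r2.max() <= 0.5 + 1e-12

    def test_window_too_small_rejected(self):
        gm = _panel([np.tile([0.0, 1.0], 10)])
        with pytest.raises(ValueError):
            prune_ld(gm, _weights(["v0"], [0.1]), window_variants=1)


class TestComputeGRS:
    def test_zero_betas_zero_scores(self):
        gm = _panel([np.tile([0.0, 1.0, 2.0], 5), np.tile([2.0, 1.0, 0.0], 5)])
        sv = compute_grs(gm, _weights(["v0", "v1"], [0.0, 0.0]), mode="sum")
        assert np.allclose(sv.values, 0.0)

    def test_single_variant_modes(self):
        gm = _panel([np.array([2.0, 0.0])])
        ws = _weights(["v0"], [0.5])
        assert compute_grs(gm, ws, mode="sum").values[0] == pytest.approx(1.0)
        assert compute_grs(gm, ws, mode="mean_per_allele").values[0] == pytest.approx(0.5)

    def test_hand_computed_dot_product(self):
        gm = _panel([np.array([1.0, 0.0]), np.array([2.0, 0.0]), np.array([0.0, 1.0])])
        ws = _weights(["v0", "v1", "v2"], [0.2, -0.1, 0.05])
        sv = compute_grs(gm, ws, mode="sum")
        assert sv.values[0] == pytest.approx(0.2 - 0.2 + 0.0)
        assert sv.values[1] == pytest.approx(0.05)

    def test_missing_dosage_imputed_to_mean(self):
        col = np.array([0.0, 1.0, 2.0, np.nan])
        gm = _panel([col])
        sv = compute_grs(gm, _weights(["v0"], [1.0]), mode="sum", impute_missing=True)
        assert sv.values[3] == pytest.approx(1.0)  # mean dosage of the observed three

    def test_all_missing_individual_flagged_nan(self):
        gm = _panel([np.array([1.0, np.nan]), np.array([2.0, np.nan])])
        sv = compute_grs(gm, _weights(["v0", "v1"], [0.1, 0.2]), mode="sum", impute_missing=False)
        assert np.isnan(sv.values[1])
        assert sv.n_used[1] == 0

    def test_empty_weights_rejected(self):
        gm = _panel([np.tile([0.0, 1.0], 5)])
        with pytest.raises(ValueError):
            compute_grs(gm, _weights([], []))

    @given(st.integers(0, 2**31 - 1))
    def test_linearity_over_disjoint_weight_sets(self, seed):
        """Scoring a concatenated weight set equals the sum of the partial scores."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 8))
        cols = [rng.integers(0, 3, size=20).astype(float) for _ in range(m)]
        gm = _panel(cols)
        betas = rng.normal(size=m)
        split = int(rng.integers(1, m))
        ids = [f"v{j}" for j in range(m)]
        full = compute_grs(gm, _weights(ids, betas), mode="sum").values
        part1 = compute_grs(gm, _weights(ids[:split], betas[:split]), mode="sum").values
        part2 = compute_grs(gm, _weights(ids[split:], betas[split:]), mode="sum").values
        np.testing.assert_allclose(full, part1 + part2, atol=1e-12)
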