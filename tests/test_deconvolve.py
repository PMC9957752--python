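"""Ratio estimator, NPC summation, hepatocyte subtraction, apportionment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hepatodecon as hd
from hepatodecon.errors import (
    ApportionmentError,
    ClippingWarning,
    EstimationError,
    InconsistencyWarning,
    InvalidArgumentError,
    MarkerInvalidError,
)
from conftest import estimate_mixture_fractions


def _profile(values, lib_id="p"):
    return hd.NormalizedProfile(lib_id, pd.Series(values))


class TestMarkerRatio:
    def test_fraction_ratio_arithmetic(self):
        tissue = _profile({"g": 1.0, "rest": 999999.0})   # t_L/T_L = 1e-6
        cell = _profile({"g": 1.0, "rest": 9999.0})       # t_C/T_C = 1e-4
        assert hd.marker_ratio("g", tissue, cell) == pytest.approx(0.01)

    def test_identical_profiles_give_unity(self, refset):
        p = refset.profiles["type0"]
        for g in refset.marker_truth["type0"][:5]:
            assert hd.marker_ratio(g, p, p) == pytest.approx(1.0)

    def test_exclusive_markers_recover_fraction_exactly(self, refset):
        lib, _ = hd.mix_whole_tissue(refset, [0.9, 0.07, 0.03], noise="none")
        tissue = hd.to_molecule_counts(lib)
        for g in refset.marker_truth["type1"]:
            r = hd.marker_ratio(g, tissue, refset.profiles["type1"])
            assert r == pytest.approx(0.07, abs=1e-12)

    def test_zero_tissue_expression_is_valid_zero(self):
        tissue = _profile({"g": 0.0, "rest": 10.0})
        cell = _profile({"g": 5.0, "rest": 5.0})
        assert hd.marker_ratio("g", tissue, cell) == 0.0

    def test_zero_or_absent_in_cell_profile_is_error(self):
        tissue = _profile({"g": 1.0, "rest": 1.0})
        with pytest.raises(MarkerInvalidError):
            hd.marker_ratio("g", tissue, _profile({"g": 0.0, "rest": 1.0}))
        with pytest.raises(MarkerInvalidError):
            hd.marker_ratio("g", tissue, _profile({"rest": 1.0}))


class TestEstimateCellFraction:
    def test_mean_of_ratios(self):
        # cell fractions are 1/3 each; tissue fractions 0.01/3, 0.01, 0.02/3
        # give per-marker ratios {0.01, 0.03, 0.02}, mean 0.02
        tissue = _profile({"a": 1.0, "b": 3.0, "c": 2.0, "bulk": 294.0})
        cell = _profile({"a": 100.0, "b": 100.0, "c": 100.0, "bulk": 0.0})
        ms = hd.MarkerSet("ct", ["a", "b", "c"], pd.Series(dtype=float))
        est = hd.estimate_cell_fraction(ms, tissue, cell)
        assert est.fraction == pytest.approx(0.02)
        assert est.n_markers == 3

    def test_pure_tissue_gives_unit_fraction_zero_dispersion(self, refset):
        p = refset.profiles["type2"]
        ms = hd.MarkerSet("type2", refset.marker_truth["type2"], pd.Series(dtype=float))
        est = hd.estimate_cell_fraction(ms, p, p)
        assert est.fraction == pytest.approx(1.0)
        assert est.dispersion == pytest.approx(0.0, abs=1e-12)

    def test_median_average_mode(self):
        tissue = _profile({"a": 1.0, "b": 3.0, "c": 20.0, "bulk": 276.0})
        cell = _profile({"a": 100.0, "b": 100.0, "c": 100.0, "bulk": 0.0})
        ms = hd.MarkerSet("ct", ["a", "b", "c"], pd.Series(dtype=float))
        est = hd.estimate_cell_fraction(ms, tissue, cell, average="median")
        assert est.fraction == pytest.approx(0.03)

    def test_invalid_markers_skipped_and_listed(self, refset):
        lib, _ = hd.mix_whole_tissue(refset, [0.5, 0.3, 0.2], noise="none")
        tissue = hd.to_molecule_counts(lib)
        genes = refset.marker_truth["type0"] + ["not_a_gene"]
        ms = hd.MarkerSet("type0", genes, pd.Series(dtype=float))
        est = hd.estimate_cell_fraction(ms, tissue, refset.profiles["type0"])
        assert est.skipped_markers == ["not_a_gene"]
        assert est.n_markers == len(refset.marker_truth["type0"])

    def test_all_markers_invalid_is_estimation_error(self, refset):
        lib, _ = hd.mix_whole_tissue(refset, [0.5, 0.3, 0.2], noise="none")
        tissue = hd.to_molecule_counts(lib)
        ms = hd.MarkerSet("type0", ["nope1", "nope2"], pd.Series(dtype=float))
        with pytest.raises(EstimationError):
            hd.estimate_cell_fraction(ms, tissue, refset.profiles["type0"])

    def test_out_of_range_estimate_clipped_with_warning(self):
        tissue = _profile({"a": 60.0, "bulk": 40.0})
        cell = _profile({"a": 30.0, "bulk": 70.0})  # ratio 2.0
        ms = hd.MarkerSet("ct", ["a"], pd.Series(dtype=float))
        with pytest.warns(ClippingWarning):
            est = hd.estimate_cell_fraction(ms, tissue, cell)
        assert est.fraction == 1.0
        assert est.raw_fraction == pytest.approx(2.0)
        assert est.clipped

    def test_poisson_noise_estimate_within_three_standard_errors(self, refset):
        lib, _ = hd.mix_whole_tissue(refset, [0.9, 0.05, 0.05], depth=1e6,
                                     noise="poisson", seed=3)
        est = estimate_mixture_fractions(refset, lib)["type1"]
        se = est.dispersion / np.sqrt(est.n_markers)
        assert abs(est.fraction - 0.05) <= 3 * se


class TestNpcAndHepatocyte:
    def test_reported_npc_fractions_sum_to_hepatocyte_96_percent(self):
        fracs = [0.003, 0.010, 0.016, 0.001, 0.010]
        ests = [
            hd.CellFractionEstimate(f"ct{i}", f, [], 1, 0.0)
            for i, f in enumerate(fracs)
        ]
        npc, hep = hd.estimate_npc_and_hepatocyte(ests)
        assert npc == pytest.approx(0.04)
        assert hep == pytest.approx(0.96)

    def test_empty_list_degenerates_to_pure_hepatocyte(self):
        npc, hep = hd.estimate_npc_and_hepatocyte([])
        assert npc == 0.0 and hep == 1.0

    def test_duplicate_types_rejected(self):
        e = hd.CellFractionEstimate("ct", 0.1, [], 1, 0.0)
        with pytest.raises(InvalidArgumentError):
            hd.estimate_npc_and_hepatocyte([e, e])

    def test_overflowing_npc_warns_and_clips(self):
        ests = [
            hd.CellFractionEstimate("a", 0.7, [], 1, 0.0),
            hd.CellFractionEstimate("b", 0.6, [], 1, 0.0),
        ]
        with pytest.warns(InconsistencyWarning):
            npc, hep = hd.estimate_npc_and_hepatocyte(ests)
        assert npc == pytest.approx(1.3)
        assert hep == 0.0

    def test_held_out_type_recovered_by_subtraction(self):
        refs = hd.make_reference_set(4, 2000, 20, 21)
        truth = [0.96, 0.02, 0.01, 0.01]
        lib, _ = hd.mix_whole_tissue(refs, truth, noise="none")
        ests = estimate_mixture_fractions(refs, lib)
        npc_ests = [ests[ct] for ct in refs.cell_types[1:]]  # hold out type0
        npc, hep = hd.estimate_npc_and_hepatocyte(npc_ests)
        assert hep == pytest.approx(truth[0], abs=1e-12)
        assert npc == pytest.approx(sum(truth[1:]), abs=1e-12)


class TestApportionGene:
    @pytest.fixture()
    def noise_free(self, refset):
        lib, truth = hd.mix_whole_tissue(refset, [0.8, 0.15, 0.05], noise="none")
        tissue = hd.to_molecule_counts(lib)
        ests = list(estimate_mixture_fractions(refset, lib).values())
        return tissue, ests, truth

    def test_exclusive_gene_apportions_entirely_to_its_type(self, refset, noise_free):
        tissue, ests, _ = noise_free
        gene = refset.marker_truth["type1"][0]
        row = hd.apportion_gene(gene, ests, refset.profiles, tissue)
        assert row.per_type_contribution["type1"] == pytest.approx(1.0, abs=1e-12)
        assert row.per_type_contribution["type0"] == 0.0
        assert row.per_type_contribution["type2"] == 0.0
        assert row.residual == pytest.approx(0.0, abs=1e-9)

    def test_shared_gene_matches_closed_form_and_conserves(self, refset, noise_free):
        tissue, ests, truth = noise_free
        fr = truth.fractions
        for gene in refset.shared_genes[:50]:
            row = hd.apportion_gene(gene, ests, refset.profiles, tissue)
            t_frac = tissue.fractions[gene]
            for ct in refset.cell_types:
                expected = fr[ct] * refset.profiles[ct].fractions[gene] / t_frac
                assert row.per_type_contribution[ct] == pytest.approx(expected, rel=1e-10)
            total = sum(row.per_type_contribution.values()) + row.residual
            assert total == pytest.approx(1.0, abs=1e-12)
            assert row.residual == pytest.approx(0.0, abs=1e-9)

    def test_zero_weight_type_contributes_nothing(self, refset):
        lib, _ = hd.mix_whole_tissue(refset, [0.7, 0.3, 0.0], noise="none")
        tissue = hd.to_molecule_counts(lib)
        ests = list(estimate_mixture_fractions(refset, lib).values())
        gene = refset.shared_genes[0]
        row = hd.apportion_gene(gene, ests, refset.profiles, tissue)
        assert row.per_type_contribution["type2"] == 0.0

    def test_absent_gene_is_apportionment_error(self, refset, noise_free):
        tissue, ests, _ = noise_free
        with pytest.raises(ApportionmentError):
            hd.apportion_gene("no_such_gene", ests, refset.profiles, tissue)

    def test_residual_assigned_to_hepatocyte_when_requested(self, refset):
        # estimate only 2 of 3 types: the missing type's share lands in the residual
        lib, _ = hd.mix_whole_tissue(refset, [0.6, 0.3, 0.1], noise="none")
        tissue = hd.to_molecule_counts(lib)
        all_ests = estimate_mixture_fractions(refset, lib)
        partial = [all_ests["type1"], all_ests["type2"]]
        profiles = {ct: refset.profiles[ct] for ct in ("type1", "type2")}
        gene = refset.shared_genes[0]
        reported = hd.apportion_gene(gene, partial, profiles, tissue,
                                     residual_policy="report")
        assigned = hd.apportion_gene(gene, partial, profiles, tissue,
                                     residual_policy="assign_hepatocyte")
        assert reported.residual > 0
        assert assigned.residual == 0.0
        assert assigned.per_type_contribution["hepatocyte"] == pytest.approx(
            reported.residual
        )


class TestEstimatorProperties:
    def test_exact_recovery_on_noise_free_mixture(self, refset):
        truth = [0.85, 0.1, 0.05]
        lib, _ = hd.mix_whole_tissue(refset, truth, noise="none")
        ests = estimate_mixture_fractions(refset, lib)
        for ct, f in zip(refset.cell_types, truth):
            assert abs(ests[ct].fraction - f) <= 1e-10

    def test_scale_invariance_of_estimates(self, refset):
        lib, _ = hd.mix_whole_tissue(refset, [0.6, 0.3, 0.1], noise="none")
        tissue = hd.to_molecule_counts(lib)
        scaled_tissue = hd.renormalize(tissue, "total")
        ms = hd.MarkerSet("type1", refset.marker_truth["type1"], pd.Series(dtype=float))
        a = hd.estimate_cell_fraction(ms, tissue, refset.profiles["type1"])
        b = hd.estimate_cell_fraction(
            ms, scaled_tissue, hd.renormalize(refset.profiles["type1"], "median")
        )
        assert a.fraction == pytest.approx(b.fraction, rel=1e-12)

    @given(delta=st.floats(min_value=0.01, max_value=0.3))
    def test_monotonicity_in_true_fraction(self, refset, delta):
        base = 0.2
        lib_lo, _ = hd.mix_whole_tissue(
            refset, [base, (1 - base) * 0.6, (1 - base) * 0.4], noise="none"
        )
        hi = base + delta
        lib_hi, _ = hd.mix_whole_tissue(
            refset, [hi, (1 - hi) * 0.6, (1 - hi) * 0.4], noise="none"
        )
        lo_est = estimate_mixture_fractions(refset, lib_lo)["type0"].fraction
        hi_est = estimate_mixture_fractions(refset, lib_hi)["type0"].fraction
        assert hi_est > lo_est

    def test_bias_shrinks_with_sequencing_depth(self, refset):
        truth = [0.75, 0.2, 0.05]
        errors = {}
        for depth in (1e4, 1e5, 1e6):
            errs = []
            for seed in range(30):
                lib, _ = hd.mix_whole_tissue(refset, truth, depth=depth,
                                             noise="poisson", seed=seed)
                est = estimate_mixture_fractions(refset, lib)["type1"]
                errs.append(est.fraction - 0.2)
            errors[depth] = np.mean(np.abs(errs))
        assert errors[1e4] > errors[1e5] > errors[1e6]
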