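"""Instrument QC cascade: clumping, F statistic, Steiger and confounder filters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrforge.errors import InvalidInputError, LDLookupError
from mrforge.selection import (
    LDMatrix,
    TraitAnnotation,
    clump,
    confounder_filter,
    f_statistic,
    fold_to_maf,
    steiger_filter,
    variance_explained,
    weak_instrument_filter,
)
from mrforge.summary_io import HarmonizedInstrument, VariantAssociation


def _var(vid, pvalue, chrom="1", pos=1_000_000):
    return VariantAssociation(vid, "A", "G", 0.1, 0.01, pvalue, eaf=0.3,
                              chrom=chrom, pos=pos)


def _ld(ids, r2_pairs):
    """Symmetric LD matrix from a {frozenset(pair): r2} map (r = sqrt(r2))."""
    n = len(ids)
    r = np.eye(n)
    for (i, j) in itertools.combinations(range(n), 2):
        r2 = r2_pairs.get(frozenset((ids[i], ids[j])), 0.0)
        r[i, j] = r[j, i] = np.sqrt(r2)
    return LDMatrix(tuple(ids), r)


def brute_force_clump(variants, ld, r2_threshold):
    """Oracle: exhaustively verify the greedy rule by direct simulation.

    Re-derives the retained set by the definition: repeatedly take the
    smallest-p remaining variant, then drop everything correlated with it
    above threshold.  Positions ignored (call with window covering all pairs).
    """
    remaining = sorted(variants, key=lambda v: (v.pvalue, v.variant_id))
    kept = []
    while remaining:
        top = remaining[0]
        kept.append(top.variant_id)
        remaining = [v for v in remaining[1:]
                     if ld.r2(top.variant_id, v.variant_id) <= r2_threshold]
    return kept


class TestClump:
    def test_single_snp_is_its_own_clump(self):
        v = _var("rs1", 1e-9)
        ld = LDMatrix.identity(["rs1"])
        assert clump([v], ld) == [v]

    def test_correlated_pair_keeps_smaller_p(self):
        a, b = _var("rsA", 1e-12, pos=1_000_000), _var("rsB", 1e-9, pos=6_000_000)
        ld = _ld(["rsA", "rsB"], {frozenset(("rsA", "rsB")): 0.5})
        retained = clump([a, b], ld, window_kb=10_000, r2_threshold=0.001)
        assert [v.variant_id for v in retained] == ["rsA"]

    def test_sub_threshold_triple_all_retained(self):
        variants = [_var(f"rs{j}", 10.0 ** -(9 + j), pos=1_000_000 + j * 1000)
                    for j in range(3)]
        pairs = {frozenset((a.variant_id, b.variant_id)): 0.0005
                 for a, b in itertools.combinations(variants, 2)}
        ld = _ld([v.variant_id for v in variants], pairs)
        retained = clump(variants, ld, window_kb=10_000, r2_threshold=0.001)
        assert sorted(v.variant_id for v in retained) == ["rs0", "rs1", "rs2"]
        assert [v.variant_id for v in retained] == brute_force_clump(
            variants, ld, 0.001)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(2, 9))
            ids = [f"rs{j}" for j in range(n)]
            variants = [_var(ids[j], float(rng.uniform(1e-12, 1e-6)),
                             pos=1_000_000 + j * 1000) for j in range(n)]
            pairs = {frozenset(p): float(rng.uniform(0, 0.01))
                     for p in itertools.combinations(ids, 2)}
            ld = _ld(ids, pairs)
            got = [v.variant_id for v in clump(variants, ld, None, 0.001)]
            assert got == brute_force_clump(variants, ld, 0.001)

    def test_out_of_window_pairs_ignored(self):
        # 50 Mb apart: outside the 10 Mb window, so high LD is irrelevant
        a, b = _var("rsA", 1e-12, pos=1_000_000), _var("rsB", 1e-9, pos=51_000_000)
        ld = _ld(["rsA", "rsB"], {frozenset(("rsA", "rsB")): 0.9})
        assert len(clump([a, b], ld)) == 2

    def test_missing_ld_pair_is_hard_error(self):
        a, b = _var("rsA", 1e-12, pos=1_000_000), _var("rsB", 1e-9, pos=2_000_000)
        ld = LDMatrix.identity(["rsA"])
        with pytest.raises(LDLookupError):
            clump([a, b], ld)

    def test_missing_position_rejected_for_windowed_clump(self):
        v = VariantAssociation("rs1", "A", "G", 0.1, 0.01, 1e-9)
        with pytest.raises(InvalidInputError):
            clump([v], LDMatrix.identity(["rs1"]), window_kb=10_000)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        ids = [f"rs{j}" for j in range(8)]
        variants = [_var(ids[j], float(rng.uniform(1e-12, 1e-6)),
                         pos=1_000_000 + j * 1000) for j in range(8)]
        pairs = {frozenset(p): float(rng.uniform(0, 0.3))
                 for p in itertools.combinations(ids, 2)}
        ld = _ld(ids, pairs)
        once = clump(variants, ld)
        twice = clump(once, ld)
        assert [v.variant_id for v in once] == [v.variant_id for v in twice]

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        ids = [f"rs{j}" for j in range(10)]
        variants = [_var(ids[j], float(rng.uniform(1e-12, 1e-6)),
                         pos=1_000_000 + j * 1000) for j in range(10)]
        pairs = {frozenset(p): float(rng.uniform(0, 0.5))
                 for p in itertools.combinations(ids, 2)}
        ld = _ld(ids, pairs)
        retained = clump(variants, ld, window_kb=10_000, r2_threshold=0.01)
        for a, b in itertools.combinations(retained, 2):
            assert ld.r2(a.variant_id, b.variant_id) <= 0.01


class TestLDMatrix:
    def test_asymmetric_rejected(self):
        r = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(InvalidInputError):
            LDMatrix(("a", "b"), r)

    def test_non_unit_diagonal_rejected(self):
        with pytest.raises(InvalidInputError):
            LDMatrix(("a", "b"), np.array([[1.0, 0.1], [0.1, 0.9]]))

    def test_read_write_round_trip(self, tmp_path):
        m = _ld(["rs1", "rs2"], {frozenset(("rs1", "rs2")): 0.25})
        path = tmp_path / "ld.tsv"
        m.write(path)
        back = LDMatrix.read(path)
        assert back.variant_ids == m.variant_ids
        np.testing.assert_allclose(back.r, m.r)


class TestFStatistic:
    def test_conservative_instrument_values(self):
        # direct arithmetic on the CRP effect sizes
        assert f_statistic(0.18, 0.01) == pytest.approx(324.0)
        assert f_statistic(0.21, 0.018) == pytest.approx(136.1, abs=0.05)

    def test_zero_beta_gives_zero(self):
        assert f_statistic(0.0, 0.5) == 0.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(InvalidInputError):
            f_statistic(0.1, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-2, 2, allow_nan=False), st.floats(0.001, 1))
    def test_doubling_beta_quadruples_f(self, beta, se):
        assert f_statistic(2 * beta, se) == pytest.approx(4 * f_statistic(beta, se))


class TestVarianceExplained:
    def test_zero_beta(self):
        assert variance_explained(0.0, 0.3) == 0.0

    def test_closed_form_max(self):
        assert variance_explained(1.0, 0.5) == pytest.approx(0.5)

    def test_maf_bounds_enforced(self):
        with pytest.raises(InvalidInputError):
            variance_explained(0.1, 0.7)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-1, 1, allow_nan=False), st.floats(0, 0.5))
    def test_doubling_beta_quadruples_r2(self, beta, maf):
        assert variance_explained(2 * beta, maf) == pytest.approx(
            4 * variance_explained(beta, maf), abs=1e-12)

    def test_generator_round_trip_recovers_target_fraction(self):
        """Summed per-SNP r2 over a synthetic set matches the truth record."""
        from mrforge.synthetic import SyntheticConfig, generate

        ds = generate(SyntheticConfig(n_snps=40, seed=5))
        truth_r2 = sum(
            variance_explained(g, m) for g, m in zip(ds.truth["gamma"], ds.truth["maf"])
        )
        est_r2 = sum(
            variance_explained(v.beta, fold_to_maf(v.eaf)) for v in ds.exposure
        )
        assert est_r2 == pytest.approx(truth_r2, rel=0.15)


def _ins(vid, bx, by, eaf_exp=0.3, eaf_out=0.3, sx=0.005, sy=0.01):
    return HarmonizedInstrument(vid, bx, sx, by, sy, eaf_exp=eaf_exp, eaf_out=eaf_out)


class TestSteigerFilter:
    def test_dominant_exposure_r2_retained(self):
        result = steiger_filter([_ins("rs1", bx=0.2, by=0.005)])
        (kept,) = result.retained
        assert kept.steiger_direction is True
        assert kept.r2_exp > kept.r2_out

    def test_tie_excluded_by_strict_inequality(self):
        result = steiger_filter([_ins("rs1", bx=0.1, by=0.1)])
        assert result.retained == []
        assert list(result.exclusions.reason) == ["steiger_direction_false"]

    def test_reverse_direction_excluded(self):
        result = steiger_filter([_ins("rs1", bx=0.01, by=0.3)])
        assert result.retained == []

    def test_missing_eaf_unevaluable(self):
        result = steiger_filter([_ins("rs1", bx=0.2, by=0.005, eaf_out=None)])
        assert result.retained == []
        assert "unevaluable" in result.exclusions.reason.iloc[0]

    def test_z_test_reported(self):
        result = steiger_filter([_ins("rs1", bx=0.2, by=0.005)])
        row = result.steiger_table.iloc[0]
        assert row.steiger_z > 0 and 0 < row.steiger_p < 1


class TestConfounderFilter:
    def test_annotated_snps_excluded(self):
        ins = [_ins(f"rs{j}", 0.2, 0.005) for j in range(53)]
        anns = [TraitAnnotation(f"rs{j}", "Total cholesterol", 1e-10) for j in range(20)]
        result = confounder_filter(ins, anns, {"Total cholesterol"}, 5e-8)
        assert len(result.retained) == 33
        assert len(result.exclusions) == 20

    def test_boundary_p_retained(self):
        ins = [_ins("rs1", 0.2, 0.005)]
        anns = [TraitAnnotation("rs1", "Total cholesterol", 5e-8)]
        result = confounder_filter(ins, anns, {"Total cholesterol"}, 5e-8)
        assert len(result.retained) == 1

    def test_empty_trait_set_retains_all(self):
        ins = [_ins("rs1", 0.2, 0.005)]
        anns = [TraitAnnotation("rs1", "Total cholesterol", 1e-10)]
        assert len(confounder_filter(ins, anns, set(), 5e-8).retained) == 1

    def test_non_confounder_trait_ignored(self):
        ins = [_ins("rs1", 0.2, 0.005)]
        anns = [TraitAnnotation("rs1", "Hair colour", 1e-30)]
        result = confounder_filter(ins, anns, {"Total cholesterol"}, 5e-8)
        assert len(result.retained) == 1


class TestWeakInstrumentFilter:
    def test_weak_snp_dropped_and_f_recorded(self):
        strong = _ins("rs1", 0.2, 0.005, sx=0.01)   # F = 400
        weak = _ins("rs2", 0.02, 0.005, sx=0.01)    # F = 4
        result = weak_instrument_filter([strong, weak], f_min=10)
        assert [i.variant_id for i in result.retained] == ["rs1"]
        assert result.retained[0].f_stat == pytest.approx(400.0)
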