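import numpy as np
import pytest

from promoterlearn import (
    PromoterRecord,
    PromoterSet,
    available_scales,
    load_scale,
    property_profile,
    region_group_comparison,
    smoothed_profile,
    uniform_scale,
    window_property_mean,
)
from promoterlearn.mechanical_profiles import PropertyScale, window_property_sum
from conftest import random_dna


class TestLoadScale:
    @pytest.mark.parametrize("name", available_scales())
    def test_packaged_scales_complete(self, name):
        scale = load_scale(name)
        assert len(scale.table) == 4 ** scale.word_length
        assert scale.source  # provenance metadata present
        assert all(np.isfinite(v) for v in scale.table.values())

    def test_packaged_scale_word_lengths(self):
        assert load_scale("deformability").word_length == 2
        assert load_scale("stiffness").word_length == 2
        assert load_scale("bendability").word_length == 3
        assert load_scale("nucleosome_preference").word_length == 3

    def test_custom_file_round_trip(self, tmp_path):
        path = tmp_path / "toy.tsv"
        lines = ["#name=toy", "#unit=u", "#source=test"]
        from itertools import product

        lines += [f"{''.join(p)}\t1.0" for p in product("ACGT", repeat=2)]
        path.write_text("\n".join(lines) + "\n")
        scale = load_scale(path)
        assert scale.name == "toy" and scale.unit == "u"
        assert set(scale.table.values()) == {1.0}

    def test_missing_word_errors_naming_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        from itertools import product

        rows = [f"{''.join(p)}\t1.0" for p in product("ACGT", repeat=2)
                if "".join(p) != "TT"]
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="TT"):
            load_scale(path)

    def test_duplicate_word_errors(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("AA\t1.0\nAA\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_scale(path)


class TestPropertyProfile:
    def test_all_ones_scale(self, ones_dinuc_scale):
        prof = property_profile("ACGTACGTAC", ones_dinuc_scale)
        assert np.array_equal(prof.values, np.ones(9))
        assert prof.positions[0] == -10 and prof.positions[-1] == -2

    def test_trinucleotide_lookup(self):
        scale = uniform_scale("t", 3, 0.0)
        scale.table["AAA"] = 2.0
        prof = property_profile("AAAA", scale)
        assert list(prof.values) == [2.0, 2.0]

    def test_matches_naive_lookup(self, rng):
        scale = load_scale("deformability")
        for _ in range(20):
            seq = random_dna(rng, 200)
            prof = property_profile(seq, scale)
            naive = [scale.table[seq[i : i + 2]] for i in range(199)]
            assert np.array_equal(prof.values, naive)

    def test_values_bounded_by_table(self, rng):
        scale = load_scale("bendability")
        lo, hi = min(scale.table.values()), max(scale.table.values())
        seq = random_dna(rng, 300)
        values = property_profile(seq, scale).values
        assert values.min() >= lo and values.max() <= hi

    def test_concatenation_agrees_away_from_junction(self, rng):
        scale = load_scale("deformability")
        s1, s2 = random_dna(rng, 50), random_dna(rng, 60)
        joint = property_profile(s1 + s2, scale).values
        assert np.array_equal(joint[:49], property_profile(s1, scale).values)
        assert np.array_equal(joint[50:], property_profile(s2, scale).values)

    def test_n_rejected(self, ones_dinuc_scale):
        with pytest.raises(ValueError, match="N"):
            property_profile("ACNT", ones_dinuc_scale)


class TestWindowSummary:
    def test_mean_of_uniform_scale(self, ones_trinuc_scale):
        assert window_property_mean("ACGTACGTAC", ones_trinuc_scale) == 1.0

    def test_mean_example(self):
        scale = uniform_scale("t", 3, 0.0)
        scale.table["AAA"] = 2.0
        assert window_property_mean("AAAT", scale) == 1.0

    def test_mean_and_sum_consistent_with_profile(self, rng):
        scale = load_scale("stiffness")
        seq = random_dna(rng, 80)
        values = property_profile(seq, scale).values
        assert window_property_mean(seq, scale) == pytest.approx(values.mean())
        assert window_property_sum(seq, scale) == pytest.approx(values.sum())

    def test_reversal_invariance_for_symmetric_scale(self, rng):
        sym = uniform_scale("sym", 2, 0.0)
        for w in list(sym.table):
            sym.table[w] = float(sum(c in "GC" for c in w))  # reversal-symmetric
        seq = random_dna(rng, 60)
        assert window_property_mean(seq, sym) == pytest.approx(
            window_property_mean(seq[::-1], sym)
        )


class TestSymmetrize:
    def test_symmetrized_scale_is_rc_invariant(self):
        scale = load_scale("deformability").symmetrize()
        comp = str.maketrans("ACGT", "TGCA")
        for w, v in scale.table.items():
            rc = w.translate(comp)[::-1]
            assert v == pytest.approx(scale.table[rc])


class TestSmoothedProfile:
    def test_half_width_zero_is_identity(self, rng, ones_dinuc_scale):
        prof = property_profile(random_dna(rng, 30), ones_dinuc_scale)
        out = smoothed_profile(prof, 0)
        assert np.array_equal(out.values, prof.values)

    def test_constant_profile_unchanged(self, ones_dinuc_scale):
        prof = property_profile("ACGTACGTACGT", ones_dinuc_scale)
        for hw in (1, 2, 5):
            assert np.allclose(smoothed_profile(prof, hw).values, 1.0)

    def test_matches_direct_neighborhood_mean(self, rng):
        scale = load_scale("deformability")
        prof = property_profile(random_dna(rng, 40), scale)
        out = smoothed_profile(prof, 2)
        for i in range(len(prof.values)):
            lo, hi = max(0, i - 2), min(len(prof.values), i + 3)
            assert out.values[i] == pytest.approx(prof.values[lo:hi].mean())


class TestRegionGroupComparison:
    @staticmethod
    def _sets(rng, n, length=120):
        return PromoterSet(
            [PromoterRecord(f"g{i}", random_dna(rng, length)) for i in range(n)]
        )

    def test_identical_groups_no_difference(self, rng):
        scale = load_scale("deformability")
        group = self._sets(rng, 10)
        other = PromoterSet([PromoterRecord(f"x{i}", rec.sequence)
                             for i, rec in enumerate(group)])
        result = region_group_comparison(group, other, scale, region=(-60, -40))
        assert result.difference == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_separating_scale_detects_composition_gap(self):
        scale = uniform_scale("sep", 3, 0.0)
        scale.table["AAA"] = 1.0
        a = PromoterSet([PromoterRecord(f"a{i}", "A" * 100) for i in range(12)])
        b = PromoterSet([PromoterRecord(f"b{i}", "T" * 100) for i in range(12)])
        # inject in-region heterogeneity so the Welch variances are non-zero
        a.records[0].sequence = "A" * 45 + "C" + "A" * 54
        b.records[0].sequence = "T" * 45 + "C" + "T" * 54
        result = region_group_comparison(a, b, scale, region=(-60, -40))
        assert 0.9 < result.difference <= 1.0
        assert result.t_statistic > 0
        assert result.p_value < 1e-6

    def test_planted_shift_detected_with_reference_ttest(self, rng):
        """Welch t on per-promoter means agrees with scipy on the same means."""
        from scipy import stats

        from promoterlearn.mechanical_profiles import region_property_means

        scale = load_scale("deformability")
        a = self._sets(rng, 20)
        b = PromoterSet([
            PromoterRecord(f"b{i}", random_dna(rng, 120, p=[0.1, 0.4, 0.4, 0.1]))
            for i in range(20)
        ])
        result = region_group_comparison(a, b, scale, region=(-60, -40))
        ma, _, _ = region_property_means(a, scale, (-60, -40))
        mb, _, _ = region_property_means(b, scale, (-60, -40))
        t_ref, p_ref = stats.ttest_ind(ma, mb, equal_var=False)
        assert result.t_statistic == pytest.approx(float(t_ref))
        assert result.p_value == pytest.approx(float(p_ref))

    def test_short_promoters_dropped_and_empty_group_errors(self, rng):
        scale = load_scale("deformability")
        good = self._sets(rng, 5)
        short = PromoterSet([PromoterRecord("s", "ACGT" * 5)])  # 20 bp < region
        with pytest.raises(ValueError):
            region_group_comparison(good, short, scale, region=(-60, -40))
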