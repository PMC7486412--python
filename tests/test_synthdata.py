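"""The generator's ground truth must be recoverable by the estimators it is
meant to exercise."""

import numpy as np
import pandas as pd
import pytest

import germdiv as gd
from germdiv import qc
from germdiv.differentiation import fst_table, global_fst, windowed_fst


def _spec(**kw):
    base = dict(
        n_subpops=3, samples_per_subpop=[40, 40, 40], n_loci=400,
        drift_f=0.2, seed=1,
    )
    base.update(kw)
    return gd.PopulationSpec(**base)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_subpops": 0, "samples_per_subpop": []},
            {"n_loci": 0},
            {"drift_f": 1.0},
            {"ancestral_freq_range": (0.0, 0.9)},
            {"ancestral_freq_range": (0.9, 0.1)},
            {"missing_rate": 1.0},
            {"samples_per_subpop": [1, 0, 0]},
        ],
    )
    def test_degenerate_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            _spec(**kw)


class TestStructuredSnps:
    def test_deterministic_given_seed(self):
        a = gd.simulate_structured_snps(_spec())
        b = gd.simulate_structured_snps(_spec())
        assert np.array_equal(a.geno.dosage, b.geno.dosage, equal_nan=True)
        assert a.marker_info.equals(b.marker_info)

    def test_dosages_in_support_and_missing_rate(self):
        coll = gd.simulate_structured_snps(
            _spec(n_loci=1000, samples_per_subpop=[40, 40, 40], missing_rate=0.1)
        )
        d = coll.geno.dosage
        assert np.all(np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0)))
        assert np.isnan(d).mean() == pytest.approx(0.1, abs=0.01)

    def test_no_drift_limit_fst_near_zero(self):
        coll = gd.simulate_structured_snps(_spec(drift_f=0.0, n_loci=2000))
        fst, _ = global_fst(fst_table(coll.geno, coll.labels))
        assert abs(fst) < 0.02

    def test_balding_nichols_fst_matches_closed_form(self):
        """Realized Nei FST ~ F(K-1)/(K-F) under Beta drift (seed-averaged)."""
        k, f = 3, 0.2
        expected = f * (k - 1) / (k - f)
        vals = []
        for seed in range(5):
            coll = gd.simulate_structured_snps(
                _spec(drift_f=f, n_loci=1500, samples_per_subpop=[80] * k, seed=seed)
            )
            vals.append(global_fst(fst_table(coll.geno, coll.labels))[0])
        assert np.mean(vals) == pytest.approx(expected, abs=0.03)

    def test_frequency_conservation(self):
        """Pooled sample frequency converges to the mean of truth subpop
        frequencies."""
        coll = gd.simulate_structured_snps(
            _spec(samples_per_subpop=[300, 300, 300], n_loci=300)
        )
        pooled = gd.allele_frequencies(coll.geno).p_alt
        truth_mean = coll.truth.subpop_freqs.mean(axis=0)
        assert np.abs(pooled - truth_mean).mean() < 0.02

    def test_registry_sorted_within_chromosome(self):
        coll = gd.simulate_structured_snps(_spec())
        for _, grp in coll.marker_info.groupby("chrom", observed=True):
            bp = grp["bp"].to_numpy(dtype=float)
            assert (np.diff(bp) >= 0).all()

    def test_admixture_recorded(self):
        coll = gd.simulate_structured_snps(_spec(admixture_fraction=0.1))
        assert len(coll.truth.admixed) == round(0.1 * 120)


class TestSweeps:
    def test_empty_sweep_list_is_identity(self, small_collection):
        out = gd.apply_sweeps(small_collection, [])
        assert out is small_collection

    def test_unknown_chromosome_rejected(self, small_collection):
        sw = gd.SweepSpec("9Z", 0, 10, 0.3)
        with pytest.raises(ValueError, match="9Z"):
            gd.apply_sweeps(small_collection, [sw])

    def test_loci_outside_window_untouched(self):
        coll = gd.simulate_structured_snps(_spec(n_chromosomes=1))
        sw = gd.SweepSpec("1A", 10_000_000, 20_000_000, 0.3)
        out = gd.apply_sweeps(coll, [sw])
        bp = coll.marker_info["bp"].to_numpy(dtype=float)
        outside = (bp < 10_000_000) | (bp >= 20_000_000)
        assert np.array_equal(
            coll.geno.dosage[:, outside], out.geno.dosage[:, outside], equal_nan=True
        )
        assert not np.array_equal(
            coll.geno.dosage[:, ~outside], out.geno.dosage[:, ~outside], equal_nan=True
        )

    def test_clipping_keeps_frequencies_and_fst_bounded(self):
        coll = gd.simulate_structured_snps(_spec(n_chromosomes=1, ancestral_freq_range=(0.7, 0.9)))
        sw = gd.SweepSpec("1A", 0, 100_000_000, 1.0)
        out = gd.apply_sweeps(coll, [sw])
        assert out.truth.subpop_freqs.min() >= 0.0
        assert out.truth.subpop_freqs.max() <= 1.0
        tab = fst_table(out.geno, out.labels)
        assert np.nanmax(tab["F_ST"].to_numpy()) <= 1.0 + 1e-12

    def test_sweep_window_fst_exceeds_genome_median(self):
        hits = 0
        for seed in range(5):
            spec = gd.PopulationSpec(2, [50, 50], 2000, drift_f=0.05, seed=seed, n_chromosomes=1)
            coll = gd.apply_sweeps(
                gd.simulate_structured_snps(spec),
                [gd.SweepSpec("1A", 40_000_000, 41_000_000, 0.4)],
            )
            prof = windowed_fst(coll.geno, coll.marker_info, coll.labels)
            inside = prof[(prof["start"] == 40_000_000)]
            if len(inside) and inside["weighted_fst"].iloc[0] > prof["weighted_fst"].median():
                hits += 1
        assert hits == 5


class TestPresenceAbsence:
    def test_prob_one_gives_unit_jaccard(self):
        spec = _spec(missing_rate=0.0)
        p = gd.simulate_presence_absence(spec, 1.0)
        sim = gd.jaccard_matrix(p)
        assert np.allclose(sim.values, 1.0)

    def test_disjoint_profiles_zero_similarity(self):
        spec = gd.PopulationSpec(2, [5, 5], 100, drift_f=0.1, seed=2)
        prob = np.zeros((2, 100))
        prob[0, :50] = 1.0
        prob[1, 50:] = 1.0
        p = gd.simulate_presence_absence(spec, prob)
        sim = gd.jaccard_matrix(p)
        assert np.allclose(sim.values[:5, 5:], 0.0)

    def test_half_prob_jaccard_one_third(self):
        spec = gd.PopulationSpec(2, [20, 20], 3000, drift_f=0.1, seed=3)
        p = gd.simulate_presence_absence(spec, 0.5)
        sim = gd.jaccard_matrix(p)
        off = sim.values[np.triu_indices(sim.n, k=1)]
        assert off.mean() == pytest.approx(1 / 3, abs=0.05)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            gd.simulate_presence_absence(_spec(), 1.5)


class TestLinkageMaps:
    def _true_map(self, n=60, chroms=("1A", "2B")):
        rng = np.random.default_rng(9)
        per = n // len(chroms)
        rows, idx = [], []
        for ci, c in enumerate(chroms):
            pos = np.sort(rng.uniform(0, 150, per))
            for j, p in enumerate(pos):
                idx.append(f"MK{ci}_{j}")
                rows.append((c, p))
        return pd.DataFrame(rows, columns=["chrom", "cM"], index=idx)

    def test_zero_noise_identity_scale_is_exact_submap(self):
        tm = self._true_map()
        maps, warns = gd.simulate_linkage_maps(tm, 1, 1.0, 0.0, 0.0, seed=4)
        assert not warns
        for m in maps:
            truth = tm.loc[m.markers, "cM"].to_numpy()
            # a = exp(0) = 1 under zero distortion; b is a shift
            shifted = m.positions - m.positions[0]
            assert np.allclose(shifted, truth - truth[0], atol=1e-9)

    def test_affine_distortion_preserves_order(self):
        from scipy import stats

        tm = self._true_map()
        maps, _ = gd.simulate_linkage_maps(tm, 4, 0.7, 0.3, 0.0, seed=5)
        for m in maps:
            rho = stats.spearmanr(m.positions, tm.loc[m.markers, "cM"].to_numpy()).statistic
            assert rho == pytest.approx(1.0)

    def test_deterministic_and_min_three_markers(self):
        tm = self._true_map()
        a, _ = gd.simulate_linkage_maps(tm, 3, 0.2, 0.1, 0.5, seed=6)
        b, _ = gd.simulate_linkage_maps(tm, 3, 0.2, 0.1, 0.5, seed=6)
        for ma, mb in zip(a, b):
            assert ma.markers == mb.markers
            assert np.allclose(ma.positions, mb.positions)
            assert len(ma.markers) >= 3

    def test_tiny_chromosome_warns(self):
        tm = pd.DataFrame(
            {"chrom": ["1A", "1A"], "cM": [0.0, 5.0]}, index=["a", "b"]
        )
        _, warns = gd.simulate_linkage_maps(tm, 1, 1.0, 0.0, 0.0, seed=7)
        assert warns and "1A" in warns[0]


class TestPloidyInjection:
    def test_fraction_zero_flags_nothing(self, small_collection):
        out = gd.inject_misclassified_ploidy(small_collection, 0.0, seed=1)
        assert out.truth.misclassified == []
        fr = qc.genome_fractions(out.geno, out.marker_info)
        flags = qc.classify_ploidy(fr, out.passport["ploidy"])
        assert (flags["flag"] == "consistent").all()

    def test_exact_recovery_of_injected_fraction(self):
        coll = gd.simulate_structured_snps(
            _spec(samples_per_subpop=[100, 100, 100], n_loci=600)
        )
        out = gd.inject_misclassified_ploidy(coll, 0.05, seed=2)
        assert len(out.truth.misclassified) == 15
        fr = qc.genome_fractions(out.geno, out.marker_info)
        flags = qc.classify_ploidy(fr, out.passport["ploidy"])
        flagged = set(flags.index[flags["flag"] != "consistent"])
        assert flagged == set(out.truth.misclassified)

    def test_fraction_one_all_flagged(self):
        coll = gd.simulate_structured_snps(_spec())
        out = gd.inject_misclassified_ploidy(coll, 1.0, seed=3)
        fr = qc.genome_fractions(out.geno, out.marker_info)
        flags = qc.classify_ploidy(fr, out.passport["ploidy"])
        # every sample declared tetraploid with ~1/3 D markers -> all suspect
        assert (flags["flag"] == "suspect_tetraploid").all()
        assert flags["strong"].all()

    def test_requires_d_markers(self):
        spec = _spec(n_chromosomes=2)  # chromosomes 1A, 1B only
        coll = gd.simulate_structured_snps(spec)
        with pytest.raises(ValueError, match="D-genome"):
            gd.inject_misclassified_ploidy(coll, 0.1, seed=1)
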