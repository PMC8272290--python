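import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chronotome.io_formats import ValidationError
from chronotome.rhythm import (
    circular_phase_difference,
    cluster_genes,
    compare_phase_amplitude,
    cosinor_fit,
    cross_cultivar_intersection,
    fit_profiles,
    label_cluster_phases,
    same_cluster_fraction,
    scale_profiles,
)
from chronotome.synthetic import (
    CultivarEffect,
    RhythmSpec,
    default_phase_groups,
    generate_annotation,
    generate_expression,
)
from conftest import make_matrix

GRID = (48, 51, 54, 57, 60, 63, 66, 69)


class TestScaleProfiles:
    def test_standardization_mean_zero_sd_one(self):
        m = make_matrix({"g": [1, 2, 3, 4, 5, 6, 7, 8]})
        sp = scale_profiles(m, "HX3", log_transform=False)
        row = sp.profiles.loc["g"]
        assert abs(row.mean()) < 1e-9 and abs(row.std(ddof=1) - 1) < 1e-9

    def test_constant_profile_flagged_and_excluded(self):
        m = make_matrix({"flat": [5] * 8, "g": list(range(1, 9))})
        sp = scale_profiles(m, "HX3", log_transform=False)
        assert sp.flagged_zero_variance == ["flat"]
        assert list(sp.profiles.index) == ["g"]

    def test_affine_invariance(self):
        x = [1, 5, 2, 8, 3, 9, 4, 7]
        m1 = make_matrix({"g": x})
        m2 = make_matrix({"g": [3 * v + 10 for v in x]})
        s1 = scale_profiles(m1, "HX3", log_transform=False).profiles
        s2 = scale_profiles(m2, "HX3", log_transform=False).profiles
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)


class TestClusterGenes:
    def _make_profiles(self, noise_sd, n_per_group=50, seed=0):
        ann, _ = generate_annotation(n_per_group * 6, event_mix={}, seed=seed)
        groups = default_phase_groups(noise_sd=noise_sd)
        g, _tx, truth = generate_expression(ann, groups, seed=seed, cultivars=("HX3",))
        return scale_profiles(g, "HX3"), truth

    def test_noiseless_groups_recovered_exactly(self):
        sp, truth = self._make_profiles(noise_sd=0.0)
        asg = cluster_genes(sp, seed=0)
        ari = adjusted_rand_score(
            [truth[g] for g in asg.labels], [asg.labels[g] for g in asg.labels]
        )
        assert ari == 1.0
        # canonical naming: dawn cluster is C1, late-night is C4
        assert asg.phase_labels["C1"] == 48 and asg.phase_labels["C4"] == 69

    def test_k1_puts_all_genes_in_one_cluster(self):
        sp, _ = self._make_profiles(noise_sd=0.0, n_per_group=2)
        asg = cluster_genes(sp, k=1, seed=0)
        assert set(asg.labels.values()) == {"C1"}

    def test_fewer_profiles_than_k_rejected(self):
        m = make_matrix({"g1": list(range(8)), "g2": list(range(8))})
        sp = scale_profiles(m, "HX3", log_transform=False)
        with pytest.raises(ValidationError):
            cluster_genes(sp, k=6)


class TestPhaseLabels:
    def test_canonical_phase_name_scheme(self):
        sp, _ = TestClusterGenes()._make_profiles(noise_sd=0.0)
        asg = cluster_genes(sp, seed=0)
        names = label_cluster_phases(asg)
        assert names == {
            "C1": "dawn",
            "C2": "day",
            "C3": "dusk",
            "C5": "early-night",
            "C6": "mid-night",
            "C4": "late-night",
        }

    def test_argmax_tie_breaks_to_earliest_timepoint(self):
        values = pd.Series([1.0, 2.0, 0.0, 0.0, 0.0, 2.0, 0.0, 0.0], index=list(GRID))
        from chronotome.rhythm import _peak_timepoint

        assert _peak_timepoint(values) == 51


class TestCrossCultivar:
    def _assignment(self, labels, cultivar):
        from chronotome.rhythm import ClusterAssignment

        return ClusterAssignment(cultivar, labels, pd.DataFrame(), {})

    def test_identical_assignments_give_100_percent(self):
        labels = {f"g{i}": f"C{i % 6 + 1}" for i in range(60)}
        a = self._assignment(labels, "HX3")
        b = self._assignment(dict(labels), "ZH24")
        _, frac = cross_cultivar_intersection(a, b)
        assert frac == 100.0

    def test_disjoint_permutation_gives_zero(self):
        perm = {"C1": "C2", "C2": "C3", "C3": "C4", "C4": "C5", "C5": "C6", "C6": "C1"}
        labels = {f"g{i}": f"C{i % 6 + 1}" for i in range(60)}
        a = self._assignment(labels, "HX3")
        b = self._assignment({g: perm[l] for g, l in labels.items()}, "ZH24")
        _, frac = cross_cultivar_intersection(a, b)
        assert frac == 0.0

    def test_observed_study_table_fraction(self):
        # diagonal 19,017 of 46,188 genes in the same cluster -> 41.2 %
        table = pd.DataFrame(np.zeros((6, 6), dtype=int),
                             index=[f"C{i}" for i in range(1, 7)],
                             columns=[f"C{i}" for i in range(1, 7)])
        diag = [3170, 3170, 3170, 3169, 3169, 3169]  # sums to 19,017
        off_total = 46188 - 19017
        for i, lab in enumerate(table.index):
            table.loc[lab, lab] = diag[i]
        table.iloc[0, 1] = off_total
        assert same_cluster_fraction(table) == 41.2


class TestCosinor:
    def test_noiseless_cosine_recovered_exactly(self):
        t = np.array(GRID, dtype=float)
        x = 10 + 2 * np.cos(2 * np.pi * (t - 63) / 24)
        fit = cosinor_fit(t, x)
        assert abs(fit.amplitude - 2) < 1e-9
        assert abs(fit.acrophase - 15) < 1e-9  # 63 mod 24
        assert fit.rss < 1e-18 and not fit.flagged_flat

    def test_constant_signal_flagged_flat(self):
        fit = cosinor_fit(np.array(GRID, float), np.full(8, 7.0))
        assert fit.flagged_flat and fit.amplitude < 1e-9
        assert fit.mesor == pytest.approx(7.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            cosinor_fit([0, 8, 16], [1, 2, 3])

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(0)
        t = np.array(GRID, dtype=float)
        x = 10 + 3 * np.cos(2 * np.pi * (t - 55) / 24) + rng.normal(0, 0.5, 8)
        fit = cosinor_fit(t, x)
        # dense grid search over (mesor, amplitude, acrophase)
        best = (np.inf, None, None)
        for amp in np.arange(0, 6, 0.01):
            for phi in np.arange(0, 24, 0.05):
                pred = amp * np.cos(2 * np.pi * (t - phi) / 24)
                mesor = (x - pred).mean()
                rss = np.sum((x - mesor - pred) ** 2)
                if rss < best[0]:
                    best = (rss, amp, phi)
        assert abs(fit.amplitude - best[1]) <= 0.01
        assert abs(circular_phase_difference(fit.acrophase, best[2] % 24)) <= 0.05


class TestPhaseAmplitudeComparison:
    def test_identical_fits_give_zero_shift_unit_ratio(self):
        t = np.array(GRID, float)
        x = 10 + 2 * np.cos(2 * np.pi * (t - 63) / 24)
        fit = cosinor_fit(t, x)
        out = compare_phase_amplitude({"g": fit}, {"g": fit})
        assert out.loc["g", "delta_acrophase_h"] == 0.0
        assert out.loc["g", "amplitude_ratio"] == 1.0

    def test_circular_difference_wraps(self):
        assert circular_phase_difference(20, 2, period=24) == pytest.approx(6.0)
        assert circular_phase_difference(2, 20, period=24) == pytest.approx(-6.0)
        assert circular_phase_difference(0, 12, period=24) == pytest.approx(12.0)

    def test_planted_phase_modulation_recovered(self):
        ann, _ = generate_annotation(200, event_mix={}, seed=21)
        genes = sorted(ann)
        shifted = set(genes[:50])
        groups = default_phase_groups(noise_sd=0.1)
        effects = {"ZH24": {g: CultivarEffect(phase_shift=6.0) for g in shifted}}
        g, _tx, _ = generate_expression(ann, groups, cultivar_effects=effects, seed=22)
        fits_a = fit_profiles(g.replicate_mean("HX3"))
        fits_b = fit_profiles(g.replicate_mean("ZH24"))
        out = compare_phase_amplitude(fits_a, fits_b, genes=sorted(shifted))
        assert abs(out["delta_acrophase_h"].median() - 6.0) <= 1.0
        assert abs(out["amplitude_ratio"].median() - 1.0) <= 0.1

    def test_flat_fit_flagged_in_comparison(self):
        t = np.array(GRID, float)
        fit = cosinor_fit(t, 10 + 2 * np.cos(2 * np.pi * (t - 63) / 24))
        flat = cosinor_fit(t, np.full(8, 10.0))
        out = compare_phase_amplitude({"g": fit}, {"g": flat})
        assert bool(out.loc["g", "flagged"])
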