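"""Membrane/cytoplasm ratios, per-experiment normalization, group aggregates."""

import numpy as np
import pytest

import traffickit as tk
from traffickit.contours import RadialProfile
from traffickit.errors import NormalizationError
from traffickit.metrics import summaries_to_frame


def make_profile(values, cell_id=1, total=None):
    """Profile with given corrected band means on indices -20..39 (raw = corrected)."""
    corrected = {i: values.get(i, np.nan) for i in range(-20, 40)}
    n_pixels = {i: (8 if np.isfinite(corrected[i]) else 0) for i in corrected}
    return RadialProfile(
        cell_id=cell_id,
        raw=dict(corrected),
        corrected=corrected,
        background_value=0.0,
        total_cell_fluor=total if total is not None else float(np.nanmean(list(values.values()))),
        n_pixels=n_pixels,
    )


class TestMcRatio:
    def test_uniform_profile_gives_ratio_1(self):
        prof = make_profile({i: 42.0 for i in range(0, 40)})
        s = tk.mc_ratio(prof)
        assert s.mc_ratio == pytest.approx(1.0) and s.valid

    def test_two_level_profile(self):
        vals = {i: (20.0 if i <= 5 else 10.0) for i in range(0, 40)}
        s = tk.mc_ratio(make_profile(vals))
        assert s.membrane_mean == pytest.approx(20.0)
        assert s.cytoplasm_mean == pytest.approx(10.0)
        assert s.mc_ratio == pytest.approx(2.0)

    def test_nonpositive_cytoplasm_flagged_invalid(self):
        vals = {i: (20.0 if i <= 5 else -1.0) for i in range(0, 40)}
        s = tk.mc_ratio(make_profile(vals))
        assert not s.valid and np.isnan(s.mc_ratio)

    def test_missing_bands_excluded(self):
        vals = {i: 10.0 for i in range(0, 12)}  # bands 12..39 empty after erosion
        s = tk.mc_ratio(make_profile(vals))
        assert s.cytoplasm_mean == pytest.approx(10.0)

    def test_empty_range_raises(self):
        with pytest.raises(ValueError, match="no non-missing"):
            tk.mc_ratio(make_profile({i: 10.0 for i in range(0, 6)}))

    def test_sum_method_weights_by_pixels(self):
        prof = make_profile({i: (20.0 if i <= 5 else 10.0) for i in range(0, 40)})
        prof.n_pixels[0] = 80  # heavy band 0
        s_mean = tk.mc_ratio(prof, method="mean")
        s_sum = tk.mc_ratio(prof, method="sum")
        assert s_mean.membrane_mean == s_sum.membrane_mean == pytest.approx(20.0)
        prof.corrected[0] = 50.0
        assert tk.mc_ratio(prof, method="sum").membrane_mean > tk.mc_ratio(prof, method="mean").membrane_mean

    def test_ratio_recovery_on_noisy_field(self):
        """3:1 cells with shot noise: measured group ratio tracks the
        noise-free oracle within a few percent."""
        spec = tk.FieldSpec(image_shape=(512, 512), n_cells=25, seed=21)
        truths = tk.random_truths(spec, 300.0, 100.0, membrane_width_px=5)
        field, truths = tk.render_field(spec, truths)
        profiles, _ = tk.profile_field(field)
        est = np.mean([s.mc_ratio for s in tk.summarize_cells(profiles) if s.valid])
        import dataclasses
        spec0 = dataclasses.replace(spec, poisson_noise=False, gaussian_noise_sd=0.0)
        field0, _ = tk.render_field(spec0, truths)
        profiles0, _ = tk.profile_field(field0)
        oracle = np.mean([s.mc_ratio for s in tk.summarize_cells(profiles0)])
        assert est == pytest.approx(oracle, rel=0.10)


class TestNormalizeByExperiment:
    def test_single_cell_normalizes_to_1(self):
        prof = make_profile({i: 80.0 for i in range(0, 40)}, total=80.0)
        normed, normalizer = tk.normalize_by_experiment([prof])
        assert normalizer == 80.0
        assert normed[0].total_cell_fluor == pytest.approx(1.0)

    def test_scale_invariance(self):
        profs = [make_profile({i: 50.0 + c for i in range(0, 40)}, cell_id=c, total=50.0 + c)
                 for c in (1, 2, 3)]
        scaled = [make_profile({i: 7 * (50.0 + c) for i in range(0, 40)}, cell_id=c,
                               total=7 * (50.0 + c)) for c in (1, 2, 3)]
        a, _ = tk.normalize_by_experiment(profs)
        b, _ = tk.normalize_by_experiment(scaled)
        for x, y in zip(a, b):
            for i in x.corrected:
                if np.isfinite(x.corrected[i]):
                    assert x.corrected[i] == pytest.approx(y.corrected[i], abs=1e-12)

    def test_mean_total_is_1_after_normalization(self):
        profs = [make_profile({i: float(c) for i in range(0, 40)}, cell_id=c, total=float(c))
                 for c in (10, 20, 60)]
        normed, _ = tk.normalize_by_experiment(profs)
        assert np.mean([p.total_cell_fluor for p in normed]) == pytest.approx(1.0)

    def test_gain_factor_between_experiments(self):
        """Two experiments differing by a 2.5x gain give matching normalized profiles."""
        spec = tk.FieldSpec(image_shape=(256, 256), n_cells=3, poisson_noise=False,
                            gaussian_noise_sd=0.0, background_level=0.0, seed=31)
        truths = tk.random_truths(spec, 300.0, 100.0)
        f1, _ = tk.render_field(spec, truths)
        f2 = tk.LabeledField(f1.intensity * 2.5, f1.labels)
        p1, _ = tk.profile_field(f1)
        p2, _ = tk.profile_field(f2)
        n1, _ = tk.normalize_by_experiment(p1)
        n2, _ = tk.normalize_by_experiment(p2)
        for a, b in zip(n1, n2):
            for i in a.corrected:
                if np.isfinite(a.corrected[i]):
                    assert a.corrected[i] == pytest.approx(b.corrected[i], abs=1e-9)

    def test_nonpositive_normalizer_rejected(self):
        with pytest.raises(NormalizationError):
            tk.normalize_by_experiment([])
        prof = make_profile({i: 0.0 for i in range(0, 40)}, total=0.0)
        with pytest.raises(NormalizationError):
            tk.normalize_by_experiment([prof])


class TestAggregate:
    def summaries(self, ratios, condition="control", genotype="WT", experiment_id="e1"):
        return [
            tk.CellSummary(cell_id=i + 1, membrane_mean=r, cytoplasm_mean=1.0, mc_ratio=r,
                           total_cell_fluor=1.0, condition=condition, genotype=genotype,
                           experiment_id=experiment_id)
            for i, r in enumerate(ratios)
        ]

    def test_single_cell_group_sem_zero_flagged(self):
        frame, _ = tk.aggregate(self.summaries([2.0]))
        assert frame.loc[0, "ratio_sem_cells"] == 0.0
        assert bool(frame.loc[0, "n_is_1"])

    def test_duplicated_cell_sem_zero(self):
        frame, _ = tk.aggregate(self.summaries([3.0, 3.0]))
        assert frame.loc[0, "ratio_mean"] == pytest.approx(3.0)
        assert frame.loc[0, "ratio_sem_cells"] == 0.0

    def test_invalid_cells_counted_not_averaged(self):
        cells = self.summaries([2.0, 4.0])
        cells.append(tk.CellSummary(cell_id=9, membrane_mean=1.0, cytoplasm_mean=-1.0,
                                    mc_ratio=float("nan"), total_cell_fluor=1.0,
                                    condition="control", genotype="WT",
                                    experiment_id="e1", valid=False))
        frame, _ = tk.aggregate(cells)
        assert frame.loc[0, "ratio_mean"] == pytest.approx(3.0)
        assert frame.loc[0, "n_invalid"] == 1

    def test_empty_group_omitted_with_warning(self):
        cells = self.summaries([2.0]) + [
            tk.CellSummary(cell_id=5, membrane_mean=1.0, cytoplasm_mean=-1.0,
                           mc_ratio=float("nan"), total_cell_fluor=1.0,
                           condition="stim", genotype="WT", experiment_id="e1", valid=False)
        ]
        with pytest.warns(UserWarning, match="no valid cells"):
            frame, _ = tk.aggregate(cells)
        assert list(frame["condition"]) == ["control"]

    def test_sem_across_experiments_emitted(self):
        cells = (self.summaries([2.0, 2.2], experiment_id="e1")
                 + self.summaries([2.6, 2.8], experiment_id="e2"))
        frame, _ = tk.aggregate(cells)
        per_exp = np.array([2.1, 2.7])
        expected = per_exp.std(ddof=1) / np.sqrt(2)
        assert frame.loc[0, "ratio_sem_experiments"] == pytest.approx(expected)
        assert frame.loc[0, "n_experiments"] == 2

    def test_band_profile_aggregation(self):
        profiles = tk.io.profiles_to_frame(
            [make_profile({i: 10.0 for i in range(0, 40)}, cell_id=1),
             make_profile({i: 20.0 for i in range(0, 40)}, cell_id=2)],
            "e1", "control", "WT",
        )
        _, group = tk.aggregate(self.summaries([1.0, 1.0]), profiles)
        band0 = group[group["band_index"] == 0]
        assert band0["mean"].iloc[0] == pytest.approx(15.0)
        assert band0["n"].iloc[0] == 2

    def test_monte_carlo_coverage_of_group_mean(self):
        """Group mean ± 2·SEM covers the true mean at the nominal ~95% rate.

        Expected coverage of a 2·SEM interval at n=200 is ~95.4%; over 100
        replicates the binomial 3-sigma floor is ~89, so >=90 hits confirms a
        correctly scaled SEM (an SEM off by sqrt(2) would cover ~84%).
        """
        rng = np.random.default_rng(77)
        true_mean, hits, n_rep = 3.0, 0, 100
        for _ in range(n_rep):
            ratios = rng.normal(true_mean, 0.5, size=200)
            frame, _ = tk.aggregate(self.summaries(ratios))
            m, sem = frame.loc[0, "ratio_mean"], frame.loc[0, "ratio_sem_cells"]
            hits += abs(m - true_mean) <= 2 * sem
        assert hits >= 90

    def test_internalization_monotonicity(self):
        """Group mean ratio strictly decreases with internalized fraction."""
        spec = tk.FieldSpec(image_shape=(400, 400), n_cells=12, seed=41)
        truths = tk.random_truths(spec, 300.0, 100.0, membrane_width_px=5)
        _, truths = tk.render_field(spec, truths)
        means = []
        for f in (0.0, 0.5, 1.0):
            field, _ = tk.render_field(spec, tk.simulate_internalization(truths, f))
            profiles, _ = tk.profile_field(field)
            means.append(np.mean([s.mc_ratio for s in tk.summarize_cells(profiles) if s.valid]))
        assert means[0] > means[1] > means[2]

    def test_summaries_frame_columns(self):
        frame = summaries_to_frame(self.summaries([1.0]))
        assert list(frame.columns) == tk.metrics.SUMMARY_COLUMNS
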