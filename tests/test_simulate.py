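import numpy as np
import pandas as pd
import pytest

from regland import enrich as en
from regland.errors import ParameterError
from regland.simulate import (
    GroundTruth,
    ImageSimConfig,
    SimulationConfig,
    planted_patterns,
    simulate_accessibility,
    simulate_chip,
    simulate_footprints,
    simulate_sections,
    simulate_two_group,
)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,field", [
        ({"n_planted_patterns": 1}, "n_planted_patterns"),
        ({"n_replicates": 1}, "n_replicates"),
        ({"nb_dispersion": 0.0}, "nb_dispersion"),
        ({"baseline_mean": -5.0}, "baseline_mean"),
        ({"driver_correlation": 1.5}, "driver_correlation"),
        ({"frac_constitutive": 1.0}, "frac_constitutive"),
    ])
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ParameterError, match=field):
            SimulationConfig(seed=0, **kwargs)

    def test_negative_channel_mean_rejected(self):
        img = ImageSimConfig(channel_means={"p3": {"SOX2": -1.0}})
        with pytest.raises(ParameterError, match="channel_means"):
            SimulationConfig(seed=0, image=img)


class TestAccessibility:
    def test_same_seed_is_bit_identical(self):
        a = simulate_accessibility(SimulationConfig(seed=42, n_elements=120))
        b = simulate_accessibility(SimulationConfig(seed=42, n_elements=120))
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2].df.equals(b[2].df)
        assert a[3].element_pattern.equals(b[3].element_pattern)
        assert np.array_equal(a[0].qval.to_numpy(), b[0].qval.to_numpy())

    def test_structure_and_truth_alignment(self, small_sim):
        _cfg, peaks, counts, samples, truth = small_sim
        assert len(peaks) == len(counts.element_ids) == 600
        assert (counts.values.to_numpy() >= 0).all()
        assert set(counts.sample_ids) == set(samples.sample_ids)
        assert truth.element_pattern.index.equals(counts.element_ids)
        # intervals non-overlapping and sorted
        df = peaks.df
        assert (df["start"].to_numpy()[1:] >= df["end"].to_numpy()[:-1]).all()

    def test_zero_effect_gives_null_dataset(self):
        cfg = SimulationConfig(seed=5, n_elements=400, effect_log2fc=0.0)
        _p, counts, samples, truth = simulate_accessibility(cfg)
        # planted patterns carry no signal: per-element condition means
        # differ only by noise once depth is removed
        depth = counts.values.mean(axis=0)
        scaled = counts.values / depth
        pat3 = truth.element_pattern == 3
        in_open = scaled.loc[pat3].to_numpy().mean()
        rest = scaled.loc[~pat3].to_numpy().mean()
        assert in_open == pytest.approx(rest, rel=0.05)

    def test_poisson_limit_variance_mean_ratio(self):
        # all elements of one sample share mu = baseline * lib_factor,
        # so one column of null elements is an iid NB sample
        counts, _ga, _gb, _ = simulate_two_group(
            seed=9, n_elements=10_000, frac_differential=0.0,
            nb_dispersion=1e-12, baseline_mean=100.0)
        x = counts.values.iloc[:, 0].to_numpy(dtype=float)
        ratio = x.var(ddof=1) / x.mean()
        assert abs(ratio - 1.0) < 3 * np.sqrt(2.0 / len(x))

    def test_nb_moments_match_three_standard_errors(self):
        disp, n = 0.3, 10_000
        counts, _ga, _gb, _ = simulate_two_group(
            seed=10, n_elements=n, frac_differential=0.0, nb_dispersion=disp,
            baseline_mean=200.0)
        x = counts.values.iloc[:, 0].to_numpy(dtype=float)
        sigma2 = x.mean() + disp * x.mean() ** 2
        m4 = ((x - x.mean()) ** 4).mean()
        se_var = np.sqrt((m4 - x.var() ** 2) / n)
        assert abs(x.var(ddof=1) - sigma2) < 3 * se_var


class TestPlantedPatterns:
    def test_patterns_distinct_nonempty_and_named(self):
        cfg = SimulationConfig(seed=0)
        profile, names = planted_patterns(cfg)
        assert len(profile) == 9
        rows = [tuple(r) for r in profile.to_numpy()]
        assert len(set(rows)) == 9
        assert not profile.all(axis=1).any()
        assert not (~profile).all(axis=1).any()
        assert set(names) == set(profile.index)

    def test_too_many_patterns_for_design_errors(self):
        with pytest.raises(ParameterError, match="n_planted_patterns"):
            cfg = SimulationConfig(seed=0, n_planted_patterns=25)
            planted_patterns(cfg)


class TestChip:
    def test_full_enrichment_no_background_hits_exactly_targets(self,
                                                                small_sim):
        cfg, peaks, _c, _s, truth = small_sim
        chip = simulate_chip(cfg, truth, target_pattern=3, enrichment=1.0,
                             background=0.0, peaks=peaks)
        flags = en.overlaps(peaks, chip).flags
        assert flags.equals((truth.element_pattern == 3)
                            .rename("overlapped"))

    def test_partial_enrichment_within_binomial_interval(self, small_sim):
        cfg, peaks, _c, _s, truth = small_sim
        chip = simulate_chip(cfg, truth, target_pattern=2, enrichment=0.3,
                             background=0.0, peaks=peaks)
        targets = truth.element_pattern.index[truth.element_pattern == 2]
        n = len(targets)
        k = en.overlaps(peaks.subset(targets), chip).n_overlapping
        half_width = 2.58 * np.sqrt(n * 0.3 * 0.7)
        assert abs(k - 0.3 * n) <= half_width

    def test_empty_target_pattern_gives_empty_peaks(self, small_sim):
        cfg, peaks, _c, _s, truth = small_sim
        pruned = GroundTruth(
            element_pattern=truth.element_pattern.map(
                lambda p: 1 if p == 4 else p),
            pattern_profile=truth.pattern_profile,
            pattern_names=truth.pattern_names)
        chip = simulate_chip(cfg, pruned, target_pattern=4, enrichment=1.0,
                             background=0.0, peaks=peaks)
        assert len(chip) == 0

    def test_unknown_pattern_errors(self, small_sim):
        cfg, peaks, _c, _s, truth = small_sim
        with pytest.raises(ParameterError, match="pattern"):
            simulate_chip(cfg, truth, target_pattern=99, enrichment=0.5)


class TestFootprints:
    def small_cfg(self, **kw):
        return SimulationConfig(seed=kw.pop("seed", 3), n_motifs=12,
                                n_archetypes=4, n_decoys=3, **kw)

    def test_perfect_coupling_without_noise(self):
        cfg = self.small_cfg(driver_correlation=1.0, motif_noise_sd=0.0)
        truth = GroundTruth()
        table, _p, amap, rna = simulate_footprints(cfg, truth)
        from regland.footprint import archetype_scores
        scores, _ = archetype_scores(table, amap)
        for a, gene in truth.driver_tf.items():
            r = np.corrcoef(scores.loc[a], rna.loc[gene])[0, 1]
            assert r == pytest.approx(1.0)

    def test_zero_correlation_null(self):
        rs_driver, rs_decoy = [], []
        for rep in range(200):
            cfg = SimulationConfig(seed=300 + rep, n_motifs=4,
                                   n_archetypes=2, n_decoys=1,
                                   driver_correlation=0.0)
            truth = GroundTruth()
            table, _p, amap, rna = simulate_footprints(cfg, truth)
            from regland.footprint import archetype_scores
            scores, _ = archetype_scores(table, amap)
            for a, gene in truth.driver_tf.items():
                rs_driver.append(abs(np.corrcoef(scores.loc[a],
                                                 rna.loc[gene])[0, 1]))
                decoy = f"Tf{a}dec1"
                rs_decoy.append(abs(np.corrcoef(scores.loc[a],
                                                rna.loc[decoy])[0, 1]))
        assert abs(np.mean(rs_driver) - np.mean(rs_decoy)) < 0.05

    def test_singleton_archetype_score_equals_motif(self):
        cfg = SimulationConfig(seed=4, n_motifs=4, n_archetypes=4,
                               motif_noise_sd=0.1)
        table, _p, amap, _r = simulate_footprints(cfg, GroundTruth())
        from regland.footprint import archetype_scores
        scores, _ = archetype_scores(table, amap)
        for motif, a in amap.motif_to_archetype.items():
            assert np.allclose(scores.loc[a], table.loc[motif])

    def test_too_few_conditions_error(self):
        cfg = SimulationConfig(seed=0, conditions=[("p3", 5, 500),
                                                   ("p2", 5, 10)])
        with pytest.raises(ParameterError, match="3 conditions"):
            simulate_footprints(cfg, GroundTruth())


class TestSections:
    def test_fixed_seed_identical_images(self):
        img = ImageSimConfig(n_sections=1, n_nuclei=10)
        a, _ = simulate_sections(SimulationConfig(seed=17, image=img))
        b, _ = simulate_sections(SimulationConfig(seed=17, image=img))
        for ch in a[0].channels:
            assert np.array_equal(a[0].channels[ch], b[0].channels[ch])

    def test_zero_nuclei_blank_image_empty_truth(self):
        img = ImageSimConfig(n_sections=1, n_nuclei=0, noise_sd=0.0)
        stacks, truth = simulate_sections(SimulationConfig(seed=1, image=img))
        assert len(truth.nucleus_truth[0]) == 0
        assert np.allclose(stacks[0].channels["DAPI"], img.background)

    def test_all_p3_noise_free_markers_above_background(self):
        img = ImageSimConfig(n_sections=1, n_nuclei=8, noise_sd=0.0,
                             class_probs={"p3": 1.0, "V3": 0.0, "other": 0.0})
        stacks, truth = simulate_sections(SimulationConfig(seed=2, image=img))
        tt = truth.nucleus_truth[0]
        for ch in ("SOX2", "NKX2.2"):
            arr = stacks[0].channels[ch]
            for row, col in zip(tt.centroid_row, tt.centroid_col):
                assert arr[int(row), int(col)] > img.background

    def test_impossible_placement_errors(self):
        img = ImageSimConfig(n_sections=1, n_nuclei=2000, shape=(60, 60),
                             max_attempts=2000)
        with pytest.raises(ParameterError, match="place"):
            simulate_sections(SimulationConfig(seed=3, image=img))
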