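import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinmetrics.genome import GenomeModel, toy_genome
from cinmetrics.simulate import (
    CometMovieParams,
    KaryotypeParams,
    ReadDepthParams,
    simulate_bin_counts,
    simulate_cn_profiles,
    simulate_comet_movie,
    simulate_event_counts,
    simulate_karyotypes,
)


def classify_bp_by_intervals(control, knockdown, ploidy):
    """Independent interval-arithmetic oracle: bp where the knock-down CN is
    strictly nearer to / further from ploidy than the control CN."""
    closer = further = 0
    chroms = control.segments["chrom"].unique()
    for chrom in chroms:
        ca = control.segments[control.segments["chrom"] == chrom]
        cb = knockdown.segments[knockdown.segments["chrom"] == chrom]
        bounds = sorted(
            set(ca["start"]) | set(ca["end"]) | set(cb["start"]) | set(cb["end"])
        )
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            cn_a = ca[(ca["start"] <= lo) & (ca["end"] > lo)]["cn"].iloc[0]
            cn_b = cb[(cb["start"] <= lo) & (cb["end"] > lo)]["cn"].iloc[0]
            da, db = abs(cn_a - ploidy), abs(cn_b - ploidy)
            if db < da:
                closer += hi - lo
            elif db > da:
                further += hi - lo
    return closer, further


class TestGenome:
    def test_toy_genome_total_length(self):
        assert toy_genome().total_length == 720_000_000

    def test_toy_genome_has_22_autosomes(self):
        g = toy_genome()
        assert len(g.names) == 22 and g.names[0] == "chr1"

    def test_bins_tile_chromosomes(self, small_genome):
        bins = small_genome.bins()
        for name, length in zip(small_genome.names, small_genome.lengths):
            sub = bins[bins["chrom"] == name]
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == length
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()

    def test_invalid_genome_rejected(self):
        with pytest.raises(ValueError):
            GenomeModel(names=("a",), lengths=(0,), bin_size=10)
        with pytest.raises(ValueError):
            GenomeModel(names=("a",), lengths=(10,), bin_size=10, ploidy=0)


class TestSimulateCNProfiles:
    def test_identity_when_no_attenuation_no_new(self, small_genome):
        control, kd, truth = simulate_cn_profiles(small_genome, 3, 0.0, 0.0, seed=5)
        pd.testing.assert_frame_equal(control.segments, kd.segments)
        assert truth.closer_bp == 0 and truth.further_bp == 0

    def test_interval_arithmetic_oracle(self):
        # 10 alterations of 10 Mb, attenuation 0.7, new 0.3
        genome = toy_genome()
        control, kd, truth = simulate_cn_profiles(
            genome, 10, 0.7, 0.3, seed=11, alteration_length=10_000_000
        )
        assert truth.altered_bp_control == 100_000_000
        assert truth.closer_bp == 70_000_000
        assert truth.further_bp == 30_000_000
        closer, further = classify_bp_by_intervals(control, kd, genome.ploidy)
        assert closer == truth.closer_bp
        assert further == truth.further_bp

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ground_truth_matches_interval_recomputation(self, seed):
        genome = toy_genome()
        control, kd, truth = simulate_cn_profiles(genome, 8, 0.5, 0.25, seed=seed)
        closer, further = classify_bp_by_intervals(control, kd, genome.ploidy)
        assert (closer, further) == (truth.closer_bp, truth.further_bp)

    def test_determinism(self, small_genome):
        a = simulate_cn_profiles(small_genome, 3, 0.5, 0.5, seed=42)
        b = simulate_cn_profiles(small_genome, 3, 0.5, 0.5, seed=42)
        pd.testing.assert_frame_equal(a[0].segments, b[0].segments)
        pd.testing.assert_frame_equal(a[1].segments, b[1].segments)
        assert a[2] == b[2]

    def test_capacity_error_names_capacity(self, small_genome):
        with pytest.raises(ValueError, match=r"holds only \d+"):
            simulate_cn_profiles(small_genome, 1000, 0.0, 0.0, seed=0)

    def test_profiles_tile_genome_exactly(self, small_genome):
        control, kd, _ = simulate_cn_profiles(small_genome, 4, 0.5, 0.5, seed=3)
        for profile in (control, kd):
            profile.validate_against(small_genome)
            assert profile.total_bp() == small_genome.total_length

    @given(
        n_alt=st.integers(0, 3),  # genome holds 7 slots; n_alt + new slots <= 6
        att=st.floats(0, 1),
        new=st.floats(0, 1),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_length_conservation_property(self, n_alt, att, new, seed):
        genome = GenomeModel(
            names=("c1", "c2"), lengths=(40_000_000, 30_000_000), bin_size=1_000_000
        )
        control, kd, _ = simulate_cn_profiles(genome, n_alt, att, new, seed=seed)
        assert control.total_bp() == genome.total_length
        assert kd.total_bp() == genome.total_length

    def test_invalid_fractions_rejected(self, small_genome):
        with pytest.raises(ValueError):
            simulate_cn_profiles(small_genome, 1, -0.1, 0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_cn_profiles(small_genome, 1, 0.0, 1.5, seed=0)


class TestSimulateBinCounts:
    def test_noise_free_neutral_equals_mean(self, small_genome, neutral_profile):
        params = ReadDepthParams(mean_count=80.0, dispersion=0.0, seed=1)
        track = simulate_bin_counts(neutral_profile, small_genome, params)
        assert np.allclose(track.bins["count"], 80.0)

    def test_doubled_cn_doubles_expectation(self, small_genome):
        rows = [
            ("chrA", 0, 50_000_000, 4),   # 2x ploidy
            ("chrB", 0, 30_000_000, 2),
        ]
        from cinmetrics.genome import TrueCNProfile

        profile = TrueCNProfile(pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"]))
        params = ReadDepthParams(mean_count=100.0, dispersion=0.0, seed=1)
        track = simulate_bin_counts(profile, small_genome, params)
        chra = track.bins[track.bins["chrom"] == "chrA"]["count"]
        chrb = track.bins[track.bins["chrom"] == "chrB"]["count"]
        assert np.allclose(chra, 200.0) and np.allclose(chrb, 100.0)

    def test_monte_carlo_mean_recovery(self, neutral_profile):
        # ~3000 bins: empirical mean within 3% of expectation
        genome = GenomeModel(
            names=("chrA", "chrB"),
            lengths=(50_000_000, 30_000_000),
            bin_size=26_667,
            ploidy=2,
        )
        from cinmetrics.genome import TrueCNProfile

        rows = [(n, 0, l, 2) for n, l in zip(genome.names, genome.lengths)]
        profile = TrueCNProfile(pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"]))
        params = ReadDepthParams(mean_count=100.0, dispersion=0.1, seed=9)
        track = simulate_bin_counts(profile, genome, params)
        assert len(track) >= 3000
        assert abs(track.bins["count"].mean() - 100.0) / 100.0 < 0.03

    def test_gc_in_range(self, small_genome, neutral_profile):
        params = ReadDepthParams(seed=2)
        track = simulate_bin_counts(neutral_profile, small_genome, params)
        gc = track.bins["gc"]
        assert (gc >= 0.3).all() and (gc <= 0.6).all()

    def test_determinism(self, small_genome, neutral_profile):
        params = ReadDepthParams(dispersion=0.2, seed=77)
        a = simulate_bin_counts(neutral_profile, small_genome, params)
        b = simulate_bin_counts(neutral_profile, small_genome, params)
        pd.testing.assert_frame_equal(a.bins, b.bins)


class TestSimulateKaryotypes:
    def test_rate_zero_is_constant(self):
        params = KaryotypeParams(n_cells=100, base_count=52, missegregation_rate=0.0, seed=1)
        table = simulate_karyotypes(params)
        assert (table["count"] == 52).all()

    def test_base_107_mean_recovery(self):
        params = KaryotypeParams(
            n_cells=500, base_count=107, missegregation_rate=0.02, divisions=10, seed=3
        )
        table = simulate_karyotypes(params)
        assert abs(table["count"].mean() - 107) / 107 < 0.02

    def test_base_52_mean_recovery(self):
        params = KaryotypeParams(
            n_cells=500, base_count=52, missegregation_rate=0.02, divisions=10, seed=4
        )
        table = simulate_karyotypes(params)
        assert abs(table["count"].mean() - 52) / 52 < 0.02

    def test_higher_rate_more_variance(self):
        low = simulate_karyotypes(
            KaryotypeParams(n_cells=500, missegregation_rate=0.01, seed=5)
        )
        high = simulate_karyotypes(
            KaryotypeParams(n_cells=500, missegregation_rate=0.05, seed=5)
        )
        assert high["count"].var(ddof=1) > low["count"].var(ddof=1)

    def test_two_columns(self):
        table = simulate_karyotypes(KaryotypeParams(n_cells=10, seed=0))
        assert list(table.columns) == ["cell", "count"]


class TestSimulateEventCounts:
    def test_p_zero(self):
        assert simulate_event_counts(0.0, 100, seed=1) == (0, 100)

    def test_p_one(self):
        assert simulate_event_counts(1.0, 100, seed=1) == (100, 100)

    def test_binomial_interval(self):
        # 99% interval for p=0.2, n=1000: p +/- 2.576*sqrt(pq/n)
        events, n = simulate_event_counts(0.2, 1000, seed=8)
        half = 2.576 * np.sqrt(0.2 * 0.8 / 1000)
        assert abs(events / n - 0.2) < half

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            simulate_event_counts(1.1, 10, seed=0)


class TestSimulateCometMovie:
    def test_speed_zero_stationary(self):
        params = CometMovieParams(n_frames=10, n_emitters=3, speed_um_min=0.0, seed=2)
        _, truth = simulate_comet_movie(params)
        for _, sub in truth.groupby("emitter"):
            assert sub["x"].nunique() == 1 and sub["y"].nunique() == 1

    def test_unit_conversion_one_px_per_frame(self):
        # 3 um/min at 0.1 um/px every 2 s -> 1.0 px/frame
        params = CometMovieParams(
            n_frames=5, n_emitters=1, speed_um_min=3.0, pixel_size_um=0.1,
            frame_interval_s=2.0, seed=3,
        )
        stack, truth = simulate_comet_movie(params)
        sub = truth[truth["emitter"] == 0]
        steps = np.hypot(np.diff(sub["x"]), np.diff(sub["y"]))
        assert np.allclose(steps, 1.0, atol=1e-9)

    def test_noise_free_peak_matches_psf(self):
        params = CometMovieParams(
            n_frames=2, n_emitters=1, speed_um_min=0.0, noise_sd=0.0,
            background=0.0, amplitude=50.0, psf_sigma_px=2.0, seed=4,
        )
        stack, truth = simulate_comet_movie(params)
        x, y = truth.iloc[0][["x", "y"]]
        r, c = int(round(y)), int(round(x))
        expected = 50.0 * np.exp(-((r - y) ** 2 + (c - x) ** 2) / (2 * 2.0**2))
        assert stack[0, r, c] == pytest.approx(expected, rel=1e-5)
        assert stack[0].max() <= 50.0 + 1e-6

    def test_emitters_stay_in_frame(self):
        params = CometMovieParams(n_frames=90, n_emitters=20, speed_um_min=4.5, seed=5)
        _, truth = simulate_comet_movie(params)
        h, w = params.shape
        assert (truth["x"] >= 0).all() and (truth["x"] < w).all()
        assert (truth["y"] >= 0).all() and (truth["y"] < h).all()

    def test_determinism(self):
        params = CometMovieParams(n_frames=5, n_emitters=4, seed=6)
        a_stack, a_truth = simulate_comet_movie(params)
        b_stack, b_truth = simulate_comet_movie(params)
        assert np.array_equal(a_stack, b_stack)
        pd.testing.assert_frame_equal(a_truth, b_truth)

    def test_does_not_fit_raises(self):
        params = CometMovieParams(
            n_frames=90, n_emitters=1, speed_um_min=20.0, shape=(64, 64), seed=0
        )
        with pytest.raises(ValueError, match="fit"):
            simulate_comet_movie(params)
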