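import numpy as np
import pytest
from dataclasses import replace

from oriturn.io_formats import Interval, OriginSet, ReadTrack
from oriturn import origin_calling as oc
from oriturn import synthetic_data as sd
from conftest import make_flat_genome


class TestBinReads:
    def test_boundary_convention(self, toy_track):
        g = make_flat_genome(2000)
        wc = oc.bin_reads(toy_track, g, 500)
        assert wc.counts["chr1"][:4].tolist() == [2, 1, 0, 3]

    def test_empty_track_all_zero(self):
        g = make_flat_genome(2000)
        wc = oc.bin_reads(ReadTrack({"chr1": np.array([], dtype=np.int64)}), g)
        assert wc.counts["chr1"].sum() == 0
        assert len(wc.counts["chr1"]) == 4

    def test_counts_conserve_total_reads(self, small_system):
        cfg, genome, truth = small_system
        track = sd.simulate_reads(genome, truth, cfg)
        wc = oc.bin_reads(track, genome)
        assert wc.total_reads() == track.total_reads

    def test_low_mappability_windows_flagged(self):
        g = make_flat_genome(2000)
        g.mappable["chr1"] = np.array([[0, 600]])  # window 1 only 20% covered
        wc = oc.bin_reads(ReadTrack({"chr1": np.array([10])}), g, 500)
        assert wc.included("chr1").tolist() == [True, False, False, False]

    def test_invalid_window_size(self, toy_track):
        g = make_flat_genome(2000)
        with pytest.raises(ValueError):
            oc.bin_reads(toy_track, g, 0)


class TestFitBackground:
    def _window_counts(self, counts):
        n = len(counts)
        return oc.WindowCounts(500, {"chr1": np.asarray(counts)},
                               {"chr1": np.ones(n)})

    def test_poisson_counts_recovered(self):
        rng = np.random.default_rng(0)
        wc = self._window_counts(rng.poisson(14, size=20_000))
        bg = oc.fit_background(wc)
        assert bg.family == "poisson"
        assert bg.mean_per_bp * 500 == pytest.approx(14, rel=0.02)

    def test_negative_binomial_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        mu, disp = 14.0, 0.2
        r = 1.0 / disp
        counts = rng.negative_binomial(r, r / (r + mu), size=50_000)
        bg = oc.fit_background(self._window_counts(counts), trim_fraction=0.0)
        assert bg.family == "negative-binomial"
        assert bg.dispersion == pytest.approx(disp, rel=0.2)

    def test_constant_counts_zero_dispersion(self):
        bg = oc.fit_background(self._window_counts(np.full(1000, 7)))
        assert (bg.family, bg.dispersion) == ("poisson", 0.0)
        assert bg.mean_per_bp * 500 == 7

    def test_all_windows_excluded_raises(self):
        wc = oc.WindowCounts(500, {"chr1": np.ones(100, dtype=np.int64)},
                             {"chr1": np.zeros(100)})
        with pytest.raises(ValueError, match="no included windows"):
            oc.fit_background(wc)


class TestCallOrigins:
    def test_flat_background_no_calls(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(14, size=10_000)
        wc = oc.WindowCounts(500, {"chr1": counts},
                             {"chr1": np.ones(len(counts))})
        bg = oc.fit_background(wc)
        assert len(oc.call_origins(wc, bg)) == 0

    def test_single_spike_called_exactly(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(14, size=100_000)
        counts[5000] = 280  # 20x background
        wc = oc.WindowCounts(500, {"chr1": counts},
                             {"chr1": np.ones(len(counts))})
        bg = oc.fit_background(wc)
        origins = oc.call_origins(wc, bg)
        assert len(origins) == 1
        row = origins.df.iloc[0]
        assert row["start"] == 5000 * 500 and row["end"] == 5001 * 500

    def test_merge_gap_bridges_single_window(self):
        counts = np.full(1000, 10, dtype=np.int64)
        counts[100] = counts[102] = 500
        wc = oc.WindowCounts(500, {"chr1": counts}, {"chr1": np.ones(1000)})
        bg = oc.BackgroundModel("poisson", 10 / 500)
        origins = oc.call_origins(wc, bg, oc.CallerConfig(merge_gap=1))
        assert len(origins) == 1
        assert origins.df.iloc[0]["start"] == 100 * 500
        assert origins.df.iloc[0]["end"] == 103 * 500
        split = oc.call_origins(wc, bg, oc.CallerConfig(merge_gap=0))
        assert len(split) == 2

    def test_called_intervals_never_overlap(self, small_system):
        cfg, genome, truth = small_system
        track = sd.simulate_reads(genome, truth, cfg)
        origins = oc.OriginCaller().fit_predict(track, genome)
        df = origins.df.sort_values(["chrom", "start"])
        for _, sub in df.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:]
                    >= sub["end"].to_numpy()[:-1]).all()

    def test_bonferroni_more_conservative_than_fdr(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(14, size=50_000)
        counts[100:110] = 60
        wc = oc.WindowCounts(500, {"chr1": counts},
                             {"chr1": np.ones(len(counts))})
        bg = oc.BackgroundModel("poisson", 14 / 500)
        n_fdr = len(oc.call_origins(wc, bg, oc.CallerConfig(method="fdr")))
        n_bon = len(oc.call_origins(wc, bg,
                                    oc.CallerConfig(method="bonferroni")))
        assert n_bon <= n_fdr


class TestPeakLocation:
    def test_symmetric_reads_peak_at_center(self):
        reads = np.array([900, 950, 1000, 1050, 1100])
        track = ReadTrack({"chr1": reads})
        peak = oc.locate_sns_peak(Interval("chr1", 800, 1200), track)
        assert peak == 1000

    def test_single_read_peak_at_read(self):
        track = ReadTrack({"chr1": np.array([1234])})
        assert oc.locate_sns_peak(Interval("chr1", 1000, 1500), track) == 1234

    def test_no_reads_raises(self):
        track = ReadTrack({"chr1": np.array([10])})
        with pytest.raises(ValueError, match="no reads"):
            oc.locate_sns_peak(Interval("chr1", 1000, 1500), track)

    def test_unbiased_on_planted_origins(self):
        cfg = sd.SimConfig(genome_length=16_000_000, origin_density=32,
                           peak_enrichment=200 / 28.0, intensity_sigma=0.0,
                           peak_sd=100.0, seed=21)
        g = sd.make_genome(cfg)
        t = sd.plant_origins(g, cfg)
        track = sd.simulate_reads(g, t, cfg)
        errs = []
        for row in t.df.itertuples(index=False):
            c = int(row.peak)
            est = oc.locate_sns_peak(Interval(row.chrom, c - 500, c + 500),
                                     track)
            errs.append(est - c)
        errs = np.asarray(errs)
        assert len(errs) >= 400
        assert abs(errs.mean()) < 5.0
        assert np.median(np.abs(errs)) <= 25.0


class TestIntensity:
    def test_rpkm_definition(self):
        track = ReadTrack({"chr1": np.arange(10) * 100})
        track.positions["chr1"] = np.sort(np.concatenate(
            [np.linspace(0, 999, 10).astype(int),
             np.full(999_990, 10_000)]))  # pad to 1M total reads
        rpkm = oc.compute_intensity(Interval("chr1", 0, 1000), track)
        assert rpkm == pytest.approx(10.0)

    def test_doubling_total_halves_rpkm(self):
        base = ReadTrack({"chr1": np.array([10, 20, 30])})
        doubled = ReadTrack({"chr1": np.array([10, 20, 30]),
                             "chr2": np.array([5, 6, 7])})
        iv = Interval("chr1", 0, 1000)
        assert oc.compute_intensity(iv, doubled) == pytest.approx(
            oc.compute_intensity(iv, base) / 2)

    def test_zero_reads_zero_rpkm(self):
        track = ReadTrack({"chr1": np.array([5000])})
        assert oc.compute_intensity(Interval("chr1", 0, 1000), track) == 0.0


class TestSubsample:
    def test_reduces_to_target_depth(self, small_system):
        cfg, genome, truth = small_system
        track = sd.simulate_reads(genome, truth, cfg)
        sub = oc.subsample_to_depth(track, genome, 10.0, seed=5)
        assert sub.depth_per_kb(genome) == pytest.approx(10.0, rel=0.001)

    def test_subsample_is_subset_and_deterministic(self, small_system):
        cfg, genome, truth = small_system
        track = sd.simulate_reads(genome, truth, cfg)
        s1 = oc.subsample_to_depth(track, genome, 5.0, seed=6)
        s2 = oc.subsample_to_depth(track, genome, 5.0, seed=6)
        assert np.array_equal(s1.positions["chr1"], s2.positions["chr1"])
        assert np.isin(s1.positions["chr1"], track.positions["chr1"]).all()

    def test_target_equal_to_current_is_identity(self):
        g = make_flat_genome(10_000)
        track = ReadTrack({"chr1": np.arange(0, 10_000, 100)})
        out = oc.subsample_to_depth(track, g, 10.0, seed=7)
        assert np.array_equal(out.positions["chr1"], track.positions["chr1"])

    def test_target_above_depth_rejected(self):
        g = make_flat_genome(10_000)
        track = ReadTrack({"chr1": np.array([1, 2, 3])})
        with pytest.raises(ValueError, match="target depth"):
            oc.subsample_to_depth(track, g, 100.0, seed=8)


class TestConstitutiveActivity:
    def _origins(self, n=40, chrom="chr1"):
        return OriginSet([Interval(chrom, i * 5000, i * 5000 + 1000,
                                   intensity_rpkm=float(i + 1))
                          for i in range(n)])

    def test_identical_sets_fully_active(self):
        ref = self._origins()
        table = oc.constitutive_activity(ref, [ref, ref], n_classes=20)
        assert (table["fraction_active_in_all"] == 1.0).all()

    def test_disjoint_sets_inactive(self):
        ref = self._origins()
        other = OriginSet([Interval("chr2", 0, 100)])
        table = oc.constitutive_activity(ref, [other], n_classes=20)
        assert (table["fraction_active_in_all"] == 0.0).all()

    def test_intensity_dependent_sensitivity_gives_monotone_fractions(self):
        rng = np.random.default_rng(9)
        ref = self._origins(n=400)
        # detection probability grows with intensity class
        keep = [iv for iv in ref
                if rng.random() < iv.intensity_rpkm / 400.0]
        other = OriginSet(keep)
        table = oc.constitutive_activity(ref, [other], n_classes=10)
        frac = table["fraction_active_in_all"].to_numpy()
        # allow small non-monotonicities from sampling noise
        assert frac[-1] > frac[0]
        assert (np.diff(frac) > -0.25).all()

    def test_too_few_origins_rejected(self):
        with pytest.raises(ValueError):
            oc.constitutive_activity(self._origins(5), [self._origins(5)],
                                     n_classes=20)
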