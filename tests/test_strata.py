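"""Evidence tracks along the Z and changepoint segmentation into strata."""

import numpy as np
import pandas as pd
import pytest

from strataviper import pipeline, simzw, strata
from strataviper.errors import InputError, ParseError
from strataviper.strata import (WindowTrack, binary_segmentation,
                                conservation_track, depth_ratio_track,
                                divergence_track, dp_segmentation,
                                label_strata, merge_intervals, read_bed,
                                repeat_density_track,
                                repeat_divergence_profile, segment_strata,
                                segmentation_cost, toy_align_score,
                                wfragment_density_track)


@pytest.fixture(scope="module")
def viper_tracks():
    cfg = pipeline.viper_preset(seed=0)
    model = simzw.simulate_genome(cfg)
    walns = simzw.simulate_zw_alignments(model)
    dens = wfragment_density_track(
        [(s.chrom_start, s.chrom_end) for s in model.by_label("W")],
        "chrZ", cfg.z_len, 1_000_000)
    div = divergence_track(walns, "chrZ", cfg.z_len, 1_000_000)
    return cfg, model, dens, div


class TestTracks:
    def test_grid_invariants(self):
        with pytest.raises(InputError):
            WindowTrack("c", 100, np.array([0, 100, 250]), np.zeros(3))
        with pytest.raises(InputError):
            WindowTrack("c", 100, np.array([0, 100]), np.zeros(3))

    def test_depth_ratio_autosome_vs_hemizygous(self, small_bundle):
        cfg = small_bundle.config
        model = small_bundle.model
        coords = {s.id: (s.chrom, s.chrom_start) for s in model.scaffolds}
        auto_ids = [s.id for s in model.by_label("AUTO")]
        auto_median = float(np.median(
            small_bundle.depth_f.loc[
                small_bundle.depth_f["scaffold"].isin(auto_ids), "depth"]))
        z_rows = small_bundle.depth_f.loc[
            small_bundle.depth_f["scaffold"].isin(
                [s.id for s in model.by_label("Z")])]
        z_chrom = strata.project_to_chrom(z_rows, coords, "chrZ")
        track = depth_ratio_track(z_chrom, "chrZ", cfg.z_len, 100_000,
                                  auto_median)
        assert np.nanmean(track.values) == pytest.approx(0.5, abs=0.02)
        a_rows = small_bundle.depth_f.loc[
            small_bundle.depth_f["scaffold"] == auto_ids[0]]
        a_track = depth_ratio_track(
            a_rows.rename(columns={"scaffold": "chrom"}), "chr1", 100_000,
            10_000, auto_median)
        assert np.nanmean(a_track.values) == pytest.approx(1.0, abs=0.05)

    def test_par_depth_ratio_near_one(self):
        cfg = pipeline.small_preset(seed=12, par_fraction=0.2,
                                    strata_boundaries=(2_000_000, 4_000_000))
        model = simzw.simulate_genome(cfg)
        depth_f = simzw.simulate_depth(model, "F")
        coords = {s.id: (s.chrom, s.chrom_start) for s in model.scaffolds}
        z_rows = depth_f.loc[depth_f["scaffold"].isin(
            [s.id for s in model.by_label("Z")])]
        track = depth_ratio_track(
            strata.project_to_chrom(z_rows, coords, "chrZ"),
            "chrZ", cfg.z_len, 100_000, cfg.mean_depth_f)
        par_start = model.strata_map[-1][0]
        par_vals = track.values[track.starts >= par_start]
        nonpar_vals = track.values[track.starts < par_start]
        assert np.nanmean(par_vals) == pytest.approx(1.0, abs=0.03)
        assert np.nanmean(nonpar_vals) == pytest.approx(0.5, abs=0.03)

    def test_divergence_track_values(self):
        class Aln:
            def __init__(self, s, e, a, b):
                self.z_start, self.z_end = s, e
                self.seq_z, self.seq_w = a, b

        identical = Aln(0, 100, "A" * 100, "A" * 100)
        five = Aln(100, 200, "A" * 100, "A" * 95 + "C" * 5)
        track = divergence_track([identical, five], "chrZ", 300, 100)
        assert track.values[0] == 0.0
        assert track.values[1] == pytest.approx(0.05)
        assert np.isnan(track.values[2])

    def test_divergence_anchor_bounds_checked(self):
        class Aln:
            z_start, z_end = 0, 500
            seq_z = seq_w = "ACGT"

        with pytest.raises(InputError, match="anchor"):
            divergence_track([Aln()], "chrZ", 300, 100)

    def test_divergence_calibrated_per_stratum(self, viper_tracks):
        cfg, model, _, div = viper_tracks
        for start, end, name in model.strata_map:
            sel = (div.starts >= start) & (div.starts < end)
            mean = np.nanmean(div.values[sel])
            target = cfg.stratum_divergence[name]
            assert abs(mean - target) <= 0.2 * target

    def test_wfragment_density(self):
        track = wfragment_density_track([(0, 500_000)], "chrZ", 2_000_000,
                                        1_000_000)
        assert track.values.tolist() == [0.5, 0.0]
        empty = wfragment_density_track([], "chrZ", 2_000_000, 1_000_000)
        assert (empty.values == 0).all()

    def test_wdensity_young_exceeds_old(self, viper_tracks):
        cfg, model, dens, _ = viper_tracks
        segs = {name: (s, e) for s, e, name in model.strata_map}
        def seg_mean(name):
            s, e = segs[name]
            return np.nanmean(dens.values[(dens.starts >= s) & (dens.starts < e)])
        assert seg_mean("S3") > seg_mean("S2") > seg_mean("S1")

    def test_toy_align_score(self):
        assert toy_align_score("A" * 1000, "A" * 1000) == 1.0
        assert toy_align_score("A" * 1000, "C" * 1000) == -1.0
        assert np.isnan(toy_align_score("", ""))

    def test_toy_score_monotone_in_divergence(self):
        rng = np.random.default_rng(5)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        a = bases[rng.integers(0, 4, 5000)]
        scores = []
        for d in (0.0, 0.05, 0.1, 0.2):
            b = a.copy()
            hit = rng.random(a.size) < d
            idx = np.nonzero(hit)[0]
            cur = np.searchsorted(bases, b[idx])
            b[idx] = bases[(cur + rng.integers(1, 4, idx.size)) % 4]
            scores.append(toy_align_score(a.tobytes().decode(),
                                          b.tobytes().decode()))
        assert scores == sorted(scores, reverse=True)

    def test_repeat_density_merges_overlaps(self):
        bed = pd.DataFrame({
            "chrom": ["chrZ"] * 3,
            "start": [0, 25_000, 60_000],
            "end": [50_000, 50_000, 70_000],
            "name": ["Gypsy"] * 3,
            "family": ["Gypsy"] * 3,
            "divergence": [0.1] * 3,
        })
        track = repeat_density_track(bed, "chrZ", 100_000, 100_000, "Gypsy")
        assert track.values[0] == pytest.approx(0.6)  # 50k + 10k merged

    def test_genomewide_density_equals_direct_merge(self, small_bundle):
        bed = small_bundle.repeats
        cfg = small_bundle.config
        track = repeat_density_track(bed, "chrZ", cfg.z_len, 100_000, "Gypsy")
        sel = bed.loc[(bed["chrom"] == "chrZ") & (bed["family"] == "Gypsy")]
        merged = merge_intervals(list(zip(sel["start"], sel["end"])))
        covered = sum(e - s for s, e in merged)
        assert np.nansum(track.values) * 100_000 == pytest.approx(covered)

    def test_bed_parse_error_carries_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chrZ\t0\t100\nchrZ\tnope\t5\n")
        with pytest.raises(ParseError, match="line 2"):
            read_bed(p)

    def test_repeat_divergence_profile(self, small_bundle, viper_tracks):
        bed = small_bundle.repeats
        segs = [
            strata.StratumSegment(s, e, name, np.nan, np.nan)
            for s, e, name in small_bundle.model.strata_map
        ]
        profile = repeat_divergence_profile(bed, segs, chrom="chrZ")
        means = {}
        for label, df in profile.items():
            n = df["count"].sum()
            sel = bed.loc[(bed["chrom"] == "chrZ")]
            mids = (sel["start"] + sel["end"]) // 2
            seg = next(s for s in segs if s.label == label)
            direct = sel.loc[(mids >= seg.start) & (mids < seg.end)]
            assert n == len(direct)  # bin totals equal interval counts
            means[label] = np.average((df["bin_low"] + df["bin_high"]) / 2,
                                      weights=df["count"])
        assert means["S1"] > means["S3"]  # oldest stratum most diverged


class TestSegmentation:
    def test_noiseless_two_level_exact(self):
        vals = np.array([1.0] * 10 + [5.0] * 10)
        t = WindowTrack("c", 100, np.arange(20) * 100, vals)
        assert segment_strata([t], n_bkps=1) == [1000]

    def test_dp_equals_binseg_on_clear_signal(self):
        """Exact DP oracle and binary segmentation agree on 100-window
        instances with SNR >= 3."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            mu = np.concatenate([np.zeros(35), 3 * np.ones(30), 6 * np.ones(35)])
            X = (mu + rng.normal(0, 1, 100)).reshape(-1, 1)
            b = binary_segmentation(X, 2)
            d = dp_segmentation(X, 2)
            # greedy equals the exact optimum up to noise resolution: every
            # breakpoint within one window (a one-window slip on a noisy
            # boundary costs a few percent), and DP is never worse
            assert all(abs(bi - di) <= 1 for bi, di in zip(b, d))
            assert segmentation_cost(X, b) <= 1.05 * segmentation_cost(X, d)
            assert segmentation_cost(X, d) <= segmentation_cost(X, b) + 1e-9

    def test_cost_nonincreasing_in_breakpoints(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (80, 2))
        costs = [segmentation_cost(X, dp_segmentation(X, k))
                 for k in range(0, 5)]
        assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))

    def test_too_few_windows_rejected(self):
        t = WindowTrack("c", 100, np.arange(2) * 100, np.array([1.0, 2.0]))
        with pytest.raises(InputError):
            segment_strata([t], n_bkps=3)

    def test_mismatched_grids_rejected(self):
        t1 = WindowTrack("c", 100, np.arange(5) * 100, np.zeros(5))
        t2 = WindowTrack("c", 200, np.arange(5) * 200, np.zeros(5))
        with pytest.raises(InputError, match="grid"):
            segment_strata([t1, t2], n_bkps=1)

    def test_viper_boundaries_recovered(self, viper_tracks):
        cfg, _, dens, div = viper_tracks
        bkps = segment_strata([dens, div], n_bkps=2)
        assert abs(bkps[0] - 42_000_000) <= 1_000_000
        assert abs(bkps[1] - 56_000_000) <= 1_000_000

    def test_boundary_recovery_rate_over_seeds(self):
        """>= 90% of 20 seeds place both breakpoints within one window."""
        hits = 0
        for seed in range(20):
            cfg = pipeline.viper_preset(seed=seed)
            model = simzw.simulate_genome(cfg)
            dens = wfragment_density_track(
                [(s.chrom_start, s.chrom_end) for s in model.by_label("W")],
                "chrZ", cfg.z_len, 1_000_000)
            div = divergence_track(simzw.simulate_zw_alignments(model),
                                   "chrZ", cfg.z_len, 1_000_000)
            bkps = segment_strata([dens, div], n_bkps=2)
            hits += (abs(bkps[0] - 42e6) <= 1e6 and abs(bkps[1] - 56e6) <= 1e6)
        assert hits >= 18

    def test_penalty_mode_selects_plausible_k(self, viper_tracks):
        cfg, _, dens, div = viper_tracks
        bkps = segment_strata([dens, div], penalty="bic")
        assert 2 <= len(bkps) <= 4


class TestLabeling:
    def _track(self, values, window=100):
        return WindowTrack("c", window, np.arange(len(values)) * window,
                           np.asarray(values, float))

    def test_rank_by_divergence(self):
        div = self._track([0.15] * 10 + [0.25] * 10 + [0.05] * 10)
        ratio = self._track([0.5] * 30)
        segs = label_strata([1000, 2000], div, ratio)
        assert [s.label for s in segs] == ["S2", "S1", "S3"]

    def test_par_label(self):
        div = self._track([0.2] * 10 + [np.nan] * 10)
        ratio = self._track([0.5] * 10 + [1.0] * 10)
        segs = label_strata([1000], div, ratio)
        assert segs[0].label == "S1"
        assert segs[1].label == "PAR"

    def test_unranked_when_divergence_missing(self):
        div = self._track([0.2] * 10 + [np.nan] * 10)
        ratio = self._track([0.5] * 20)
        segs = label_strata([1000], div, ratio)
        assert segs[1].label == "UNRANKED"

    def test_viper_oldest_stratum_in_middle(self, viper_tracks):
        """The most diverged stratum sits at 42-56 Mb, not at an end."""
        cfg, model, dens, div = viper_tracks
        depth_like = self._track([0.5] * dens.n_windows, 1_000_000)
        bkps = segment_strata([dens, div], n_bkps=2)
        segs = label_strata(bkps, div, depth_like, chrom_len=cfg.z_len)
        s1 = next(s for s in segs if s.label == "S1")
        assert abs(s1.start - 42_000_000) <= 1_000_000
        assert abs(s1.end - 56_000_000) <= 1_000_000
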