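"""Depth normalization and homozygous-deletion calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gistmax import (
    CallerParams,
    DepthProfile,
    SimulationConfig,
    call_deletions,
    end_ratio,
    expected_ratio,
    gen_depth_profile,
    gist48_genotype,
    hom_del_cutoff,
    normalize_depths,
    scan_consecutive,
)
from gistmax.panel import Amplicon, AmpliconPanel
from gistmax.panel_cn import CutoffConflictWarning, RatioTrack


def make_track(panel, ratios, mask=None):
    ratios = np.asarray(ratios, dtype=float)
    mask = np.zeros(len(panel), dtype=bool) if mask is None else np.asarray(mask)
    return RatioTrack(ratios, mask, "median_of_ratios", "normal", "tumour")


def uniform_panel(n, gene="MAX"):
    return AmpliconPanel(
        [Amplicon("chr14", 100 * i, 100 * i + 50, gene, "exon1", i) for i in range(n)]
    )


class TestNormalizeDepths:
    def test_identical_profiles_give_unit_ratios(self, panel):
        counts = np.full(len(panel), 400)
        track = normalize_depths(
            DepthProfile("t", counts), DepthProfile("n", counts), panel
        )
        assert np.allclose(track.ratios, 1.0)

    def test_library_scale_invariance(self, panel):
        rng = np.random.default_rng(0)
        n = rng.integers(100, 900, len(panel))
        track1 = normalize_depths(DepthProfile("t", 3 * n), DepthProfile("n", n), panel)
        assert np.allclose(track1.ratios, 1.0)
        # multiplying either profile by any positive constant changes nothing
        t = rng.integers(100, 900, len(panel))
        base = normalize_depths(DepthProfile("t", t), DepthProfile("n", n), panel)
        scaled = normalize_depths(DepthProfile("t", 7 * t), DepthProfile("n", 2 * n), panel)
        assert np.allclose(base.ratios, scaled.ratios, atol=1e-9)

    def test_matches_direct_computation_oracle(self, panel):
        rng = np.random.default_rng(42)
        anchor = np.array([a.gene in ("FNTB", "FUT8") for a in panel])
        for _ in range(20):
            t = rng.integers(1, 2000, len(panel))
            n = rng.integers(1, 2000, len(panel))
            track = normalize_depths(DepthProfile("t", t), DepthProfile("n", n), panel)
            # independent direct computation: scale by the median ratio
            # over the diploid anchor genes
            raw = t / n
            expected = raw / np.median(raw[anchor])
            assert np.allclose(track.ratios, expected, atol=1e-12)

    def test_zero_normal_depth_masks_not_drops(self, panel):
        n = np.full(len(panel), 500)
        n[4] = 0
        track = normalize_depths(
            DepthProfile("t", np.full(len(panel), 500)), DepthProfile("n", n), panel
        )
        assert track.mask[4] and track.mask.sum() == 1
        assert len(track.ratios) == len(panel)
        assert not track.quality_failed

    def test_heavy_masking_sets_quality_flag(self, panel):
        n = np.full(len(panel), 500)
        n[: len(panel) // 3] = 0
        track = normalize_depths(
            DepthProfile("t", np.full(len(panel), 500)), DepthProfile("n", n), panel
        )
        assert track.quality_failed

    def test_all_zero_tumour_fails(self, panel):
        with pytest.raises(ValueError, match="no reads"):
            normalize_depths(
                DepthProfile("t", np.zeros(len(panel), dtype=int)),
                DepthProfile("n", np.full(len(panel), 500)),
                panel,
            )


class TestExpectedRatioAndCutoff:
    @pytest.mark.parametrize(
        "copy_state,purity,expected",
        [(2, 0.3, 1.0), (2, 1.0, 1.0), (0, 0.70, 0.30), (1, 0.80, 0.60), (0, 1.0, 0.0)],
    )
    def test_closed_form(self, copy_state, purity, expected):
        assert expected_ratio(copy_state, purity) == pytest.approx(expected)

    def test_monotone_decreasing_in_purity_for_loss_states(self):
        grid = np.linspace(0.05, 1.0, 20)
        for c in (0, 1):
            vals = [expected_ratio(c, t) for t in grid]
            assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(expected_ratio(2, t) == 1.0 for t in grid)

    def test_invalid_copy_state_rejected(self):
        with pytest.raises(ValueError, match="copy state"):
            expected_ratio(3, 0.8)

    @pytest.mark.parametrize(
        "fraction,cutoff", [(0.30, 0.40), (0.20, 0.30), (0.0, 0.10)]
    )
    def test_cutoff_rule(self, fraction, cutoff):
        assert hom_del_cutoff(fraction, 0.10) == pytest.approx(cutoff)

    def test_cutoff_reaching_hemizygous_expectation_warns(self):
        # at 60% non-neoplastic content the hemizygous expectation is 0.8
        with pytest.warns(CutoffConflictWarning):
            value = hom_del_cutoff(0.75, 0.15)
        assert value < expected_ratio(1, 0.25)


class TestScanConsecutive:
    def test_nine_run_called_eight_not(self):
        panel = uniform_panel(20)
        for run_len, n_calls in [(9, 1), (8, 0)]:
            ratios = np.ones(20)
            ratios[3 : 3 + run_len] = 0.2
            runs = scan_consecutive(make_track(panel, ratios), panel, 0.4, 9)
            assert len(runs) == n_calls
            if n_calls:
                assert (runs[0].first_index, runs[0].last_index) == (3, 3 + run_len - 1)
                assert runs[0].mean_ratio == pytest.approx(0.2)

    def test_uniform_track_yields_nothing(self):
        panel = uniform_panel(20)
        assert scan_consecutive(make_track(panel, np.ones(20)), panel, 0.4, 9) == []

    def test_masked_amplicon_breaks_run(self):
        panel = uniform_panel(20)
        ratios = np.full(20, 0.2)
        mask = np.zeros(20, dtype=bool)
        mask[10] = True
        runs = scan_consecutive(make_track(panel, ratios, mask), panel, 0.4, 9)
        # the mask splits one 20-run into two independent runs of 10 and 9
        assert [(r.first_index, r.last_index) for r in runs] == [(0, 9), (11, 19)]
        # a shorter left fragment would fall below min_run entirely
        mask[5] = True
        runs = scan_consecutive(make_track(panel, ratios, mask), panel, 0.4, 9)
        assert [(r.first_index, r.last_index) for r in runs] == [(11, 19)]

    @settings(max_examples=150, derandomize=True)
    @given(
        ratios=st.lists(
            st.floats(min_value=0.0, max_value=2.0, allow_nan=False), min_size=1, max_size=50
        ),
        cutoff=st.floats(min_value=0.1, max_value=1.0),
        min_run=st.integers(min_value=1, max_value=10),
    )
    def test_matches_window_enumeration_oracle(self, ratios, cutoff, min_run):
        panel = uniform_panel(len(ratios))
        track = make_track(panel, ratios)
        got = {(r.first_index, r.last_index) for r in scan_consecutive(track, panel, cutoff, min_run)}
        # oracle: enumerate every [i, j] window; keep maximal all-below windows
        n = len(ratios)
        below = [r < cutoff for r in ratios]
        expected = set()
        for i in range(n):
            for j in range(i, n):
                if all(below[i : j + 1]) and j - i + 1 >= min_run:
                    if (i == 0 or not below[i - 1]) and (j == n - 1 or not below[j + 1]):
                        expected.add((i, j))
        assert got == expected


class TestEndRatio:
    def test_uniform_track_gives_unit_statistics(self, panel):
        er = end_ratio(make_track(panel, np.ones(len(panel))), panel)
        assert er.five_prime == pytest.approx(1.0)
        assert er.three_prime == pytest.approx(1.0)

    def test_five_prime_depression_detected(self, panel):
        idx = panel.gene_indices("MAX")
        ratios = np.ones(len(panel))
        ratios[idx[:5]] = 0.3
        er = end_ratio(make_track(panel, ratios), panel)
        overall = ratios.mean()
        assert er.five_prime == pytest.approx(0.3 / overall)
        assert er.five_prime < 0.4
        assert er.three_prime == pytest.approx(1.0 / overall)

    def test_matches_arithmetic_oracle_on_random_tracks(self, panel):
        rng = np.random.default_rng(1)
        idx = panel.gene_indices("MAX")
        for _ in range(20):
            ratios = rng.uniform(0.05, 1.5, len(panel))
            er = end_ratio(make_track(panel, ratios), panel, end_size=5)
            overall = ratios.mean()
            assert er.five_prime == pytest.approx(ratios[idx[:5]].mean() / overall, abs=1e-12)
            assert er.three_prime == pytest.approx(ratios[idx[-5:]].mean() / overall, abs=1e-12)

    def test_small_gene_rejected(self, panel):
        with pytest.raises(ValueError, match="end_size"):
            end_ratio(make_track(panel, np.ones(len(panel))), panel, gene="FNTB", end_size=2)


class TestCallDeletions:
    def test_gist48_like_call_spans_exactly_exons_1_2(self, panel, max_exon12_indices):
        cfg = SimulationConfig(
            purity=0.8, genotype_map=gist48_genotype(panel),
            depth_dispersion=0.0, efficiency_sd=0.0,
        )
        t, n = gen_depth_profile(panel, cfg)
        track = normalize_depths(t, n, panel)
        calls, errors = call_deletions(track, panel, CallerParams(purity=0.8))
        assert errors == []
        assert len(calls) == 1
        call = calls[0]
        assert call.gene == "MAX" and call.zygosity == "homozygous"
        assert (call.first_index, call.last_index) == (
            max_exon12_indices[0], max_exon12_indices[-1],
        )
        assert call.mean_ratio == pytest.approx(0.2)

    def test_wild_type_yields_no_calls(self, panel):
        cfg = SimulationConfig(purity=0.8, depth_dispersion=0.0, efficiency_sd=0.0)
        t, n = gen_depth_profile(panel, cfg)
        calls, _ = call_deletions(normalize_depths(t, n, panel), panel, CallerParams(purity=0.8))
        assert calls == []

    def test_hemizygous_loss_not_called_homozygous(self, panel):
        gmap = {a.name: 1 for a in panel if a.gene == "MAX"}
        cfg = SimulationConfig(purity=0.8, genotype_map=gmap,
                               depth_dispersion=0.0, efficiency_sd=0.0)
        t, n = gen_depth_profile(panel, cfg)
        track = normalize_depths(t, n, panel)
        # hemizygous expectation 0.6 > 0.4: neither criterion may fire
        calls, _ = call_deletions(track, panel, CallerParams(cutoff=0.4))
        assert calls == []

    def test_end_ratio_criterion_fires_on_terminal_loss(self, panel):
        idx = panel.gene_indices("MAX")
        ratios = np.ones(len(panel))
        ratios[idx[:5]] = 0.35
        track = make_track(panel, ratios)
        calls, _ = call_deletions(track, panel, CallerParams(cutoff=0.3))
        # run criterion cannot fire (5 < 9; 0.35 > cutoff 0.3) but the
        # published fixed 0.4 end threshold does
        assert len(calls) == 1
        assert calls[0].criteria == ("end_ratio",)

    def test_overlapping_criteria_merge_into_one_call(self, panel):
        idx = panel.gene_indices("MAX")
        ratios = np.ones(len(panel))
        ratios[idx[:10]] = 0.1
        track = make_track(panel, ratios)
        calls, _ = call_deletions(track, panel, CallerParams(purity=0.8))
        assert len(calls) == 1
        assert set(calls[0].criteria) == {"consecutive_run", "end_ratio"}

    def test_quality_failed_track_returns_error_record(self, panel):
        mask = np.zeros(len(panel), dtype=bool)
        mask[:10] = True
        track = RatioTrack(np.ones(len(panel)), mask, "median_of_ratios", "n",
                           "t", quality_failed=True)
        calls, errors = call_deletions(track, panel, CallerParams(purity=0.8))
        assert calls == []
        assert len(errors) == 1 and "QC" in errors[0].reason


class TestRecoveryOnSimulatedCases:
    def test_sensitivity_and_false_positive_rate(self, panel):
        """>=95% sensitivity for >=9-amplicon homozygous deletions and
        <=1% false positives on wild type, at purity 0.7-0.8, depth 500."""
        span10 = gist48_genotype(panel)  # exons 1-2, 10 amplicons
        span14 = {a.name: 0 for a in panel
                  if a.gene == "MAX" and a.exon in ("exon1", "exon2", "exon3")}
        hits = 0
        false_pos = 0
        n_cases = 100
        for i in range(n_cases):
            purity = 0.7 if i % 2 else 0.8
            base = dict(mean_depth=500.0, depth_dispersion=0.002, efficiency_sd=0.15)
            cfg_del = SimulationConfig(purity=purity,
                                       genotype_map=(span10, span14)[(i // 2) % 2],
                                       seed=1000 + i, **base)
            t, n = gen_depth_profile(panel, cfg_del)
            calls, _ = call_deletions(normalize_depths(t, n, panel), panel,
                                      CallerParams(purity=purity))
            if calls:
                hits += 1
            cfg_wt = SimulationConfig(purity=purity, seed=5000 + i, **base)
            t, n = gen_depth_profile(panel, cfg_wt)
            calls, _ = call_deletions(normalize_depths(t, n, panel), panel,
                                      CallerParams(purity=purity))
            if calls:
                false_pos += 1
        assert hits / n_cases >= 0.95
        assert false_pos / n_cases <= 0.01
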