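"""Calcium pipeline: baseline estimation, transient detection, network events."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neosync import calcium as ca
from neosync import synth
from neosync.types import CaTRaster

from conftest import make_config, match_events


# --------------------------------------------------------------------------- #
# dF/F0
# --------------------------------------------------------------------------- #

class TestComputeDff:
    def test_constant_trace_gives_zero_dff(self):
        F = np.full((2, 2000), 100.0)
        t = np.arange(2000) / 10.0
        out = ca.compute_dff(F, t)
        np.testing.assert_allclose(out.dff, 0.0, atol=1e-9)

    def test_affine_trace_gives_zero_dff(self):
        # an order-2 filter reproduces polynomials up to degree 2 exactly
        t = np.arange(3000) / 10.0
        F = 50.0 + 0.1 * t
        out = ca.compute_dff(F, t)
        assert np.max(np.abs(out.dff)) < 1e-10

    def test_baseline_equals_quadratic_regression_at_window_center(self):
        rng = np.random.default_rng(0)
        F = 100.0 + rng.normal(0, 5.0, 4000)
        t = np.arange(4000) / 10.0
        out = ca.compute_dff(F, t, window_frames=1500)
        half = 1499 // 2
        for center in (half, 2000, 4000 - half - 1):
            win = F[center - half:center + half + 1]
            x = np.arange(-half, half + 1)
            coeffs = np.polyfit(x, win, 2)
            fit_at_mid = np.polyval(coeffs, 0)
            assert out.F0[0, center] == pytest.approx(fit_at_mid, rel=1e-9)

    def test_short_trace_raises_with_guidance(self):
        with pytest.raises(ValueError, match="window"):
            ca.compute_dff(np.ones(100), np.arange(100) / 10.0)

    def test_masked_frames_propagate(self):
        mask = np.zeros(2000, dtype=bool)
        mask[100:200] = True
        out = ca.compute_dff(np.full(2000, 100.0), np.arange(2000) / 10.0,
                             missing_mask=mask)
        assert np.all(np.isnan(out.dff[0, 100:200]))
        assert out.analyzed_duration == pytest.approx((2000 - 100) * 0.1)


# --------------------------------------------------------------------------- #
# transient detection
# --------------------------------------------------------------------------- #

class TestDetectCats:
    def test_false_positive_rate_on_noise(self):
        rng = np.random.default_rng(2)
        n = 200_000
        F = 100.0 * (1 + rng.normal(0, 0.02, (1, n)))
        out = ca.compute_dff(F, np.arange(n) / 10.0)
        raster = ca.detect_cats(out, threshold_sd=5.0, min_amplitude_dff=0.0)
        # Gaussian 5-sigma excursions: well under 1 onset per 1e4 frames
        assert len(raster.onsets[0]) / n < 1e-4

    def test_isolated_planted_transients_within_two_frames(self):
        # 10 well-separated transients, amplitude 0.5 dF/F, decay 1 s, SNR 10
        rng = np.random.default_rng(5)
        rate, dur = 10.0, 480.0
        n = int(dur * rate)
        planted = 20.0 + 45.0 * np.arange(10)
        s = np.zeros(n)
        kernel = 0.5 * np.exp(-np.arange(int(8 * rate)) / rate)
        for t0 in planted:
            i = int(round(t0 * rate))
            s[i:i + kernel.size] += kernel
        F = 100.0 * (1 + s) + rng.normal(0, 5.0, n)
        out = ca.compute_dff(F, np.arange(n) / rate)
        raster = ca.detect_cats(out)
        assert len(raster.onsets[0]) == 10
        np.testing.assert_allclose(raster.onsets[0], planted, atol=0.2)

    def test_random_planted_transients_recovered(self):
        traces, truth = synth.gen_calcium(make_config(
            "calcium", 480.0, 10.0, 3, n_cells=10, cell_rate_per_min=1.25,
            gdp_rate_per_min=0.0))
        out = ca.compute_dff(traces.F, traces.frame_times)
        raster = ca.detect_cats(out)
        tp = miss = extra = 0
        for c in range(10):
            r = match_events(raster.onsets[c], truth.event_times["cat"][c],
                             tol_s=0.2)
            tp, miss, extra = tp + r[0], miss + r[1], extra + r[2]
        assert tp / (tp + miss) >= 0.97
        assert tp / (tp + extra) >= 0.97

    def test_all_masked_trace_gives_empty_raster(self):
        mask = np.ones(2000, dtype=bool)
        out = ca.compute_dff(np.full((1, 2000), 100.0), np.arange(2000) / 10.0,
                             missing_mask=mask)
        raster = ca.detect_cats(out)
        assert len(raster.onsets[0]) == 0
        assert raster.analyzed_duration == 0

    def test_frequency_arithmetic(self):
        raster = CaTRaster(onsets=[np.linspace(1, 470, 11)], n_cells=1,
                           analyzed_duration=480.0)
        per_cell, mean = ca.cat_frequency(raster)
        assert mean == pytest.approx(11 / 8.0)


# --------------------------------------------------------------------------- #
# network events, with a brute-force oracle
# --------------------------------------------------------------------------- #

def oracle_gdps(onsets: list[np.ndarray], n_cells: int, window: float = 0.5,
                fraction: float = 0.20):
    """Exhaustive-interval reference: evaluates every candidate interval
    anchored at each onset (starting or ending on it) and chains all pairs."""
    events = sorted((float(t), c) for c, ts in enumerate(onsets) for t in ts)
    times = np.array([t for t, _ in events])
    cells = [c for _, c in events]
    need = fraction * n_cells - 1e-9

    starts = np.unique(np.concatenate([times, times - window]))

    def count(s):
        lo = np.searchsorted(times, s - 1e-12)
        hi = np.searchsorted(times, s + window + 1e-12, side="right")
        return len(set(cells[lo:hi]))

    good_starts = np.array([s for s in starts if count(s) >= need])
    related = [i for i, t in enumerate(times)
               if any((good_starts <= t + 1e-12)
                      & (good_starts + window >= t - 1e-12))]

    parent = {i: i for i in related}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for a in related:
        for b in related:
            if b <= a or times[b] - times[a] > window + 1e-12:
                continue
            shared = [s for s in good_starts
                      if s <= times[a] + 1e-12 and s + window >= times[b] - 1e-12]
            if shared:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups = {}
    for i in related:
        groups.setdefault(find(i), []).append(i)
    out = sorted((times[m].min(), times[m].max(),
                  frozenset(cells[i] for i in m)) for m in groups.values())
    return out


class TestDetectGdps:
    def test_twenty_percent_boundary_is_inclusive(self):
        # 2 active cells of 10 within 100 ms: exactly 20% qualifies
        onsets = [np.array([10.0]), np.array([10.1])] + [np.empty(0)] * 8
        raster = CaTRaster(onsets=onsets, n_cells=10, analyzed_duration=480.0)
        gdps = ca.detect_gdps(raster)
        assert len(gdps) == 1
        assert gdps[0].member_cells == {0, 1}
        assert gdps[0].peak_participation >= 0.2

    def test_single_active_cell_is_no_gdp(self):
        onsets = [np.array([10.0, 20.0, 30.0])] + [np.empty(0)] * 9
        raster = CaTRaster(onsets=onsets, n_cells=10, analyzed_duration=480.0)
        assert ca.detect_gdps(raster) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cells = int(rng.integers(5, 21))
        n_onsets = int(rng.integers(20, 120))
        cells = rng.integers(0, n_cells, n_onsets)
        times = rng.uniform(0, 120.0, n_onsets)
        onsets = [np.sort(times[cells == c]) for c in range(n_cells)]
        raster = CaTRaster(onsets=onsets, n_cells=n_cells, analyzed_duration=120.0)
        got = sorted((g.start, g.end, frozenset(g.member_cells))
                     for g in ca.detect_gdps(raster))
        assert got == oracle_gdps(onsets, n_cells)

    def test_lowering_fraction_is_monotone(self):
        rng = np.random.default_rng(7)
        onsets = [np.sort(rng.uniform(0, 100, 8)) for _ in range(12)]
        raster = CaTRaster(onsets=onsets, n_cells=12, analyzed_duration=100.0)
        n_related = []
        for frac in (0.5, 0.3, 0.2, 0.1):
            gdps = ca.detect_gdps(raster, fraction=frac)
            n_related.append(sum(g.n_members for g in gdps))
        assert n_related == sorted(n_related)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.floats(0.0, 1000.0),
           perm_seed=st.integers(0, 100))
    def test_invariance_under_translation_and_permutation(self, shift, perm_seed):
        rng = np.random.default_rng(11)
        onsets = [np.sort(rng.uniform(0, 60, 6)) for _ in range(10)]
        raster = CaTRaster(onsets=onsets, n_cells=10, analyzed_duration=60.0)
        base = [(g.start, g.end, frozenset(g.member_cells))
                for g in ca.detect_gdps(raster)]

        shifted = CaTRaster(onsets=[o + shift for o in onsets], n_cells=10,
                            analyzed_duration=60.0)
        got = [(g.start - shift, g.end - shift, frozenset(g.member_cells))
               for g in ca.detect_gdps(shifted)]
        assert len(got) == len(base)
        for (s1, e1, m1), (s2, e2, m2) in zip(base, got):
            assert s1 == pytest.approx(s2, abs=1e-6) and m1 == m2

        perm = np.random.default_rng(perm_seed).permutation(10)
        permuted = CaTRaster(onsets=[onsets[perm[c]] for c in range(10)],
                             n_cells=10, analyzed_duration=60.0)
        got_p = ca.detect_gdps(permuted)
        assert len(got_p) == len(base)
        mapped = sorted((g.start, g.end, frozenset(int(perm[c]) for c in g.member_cells))
                        for g in got_p)
        assert mapped == sorted(base)

    def test_gdp_frequency_arithmetic(self):
        gdps = ca.detect_gdps(CaTRaster(
            onsets=[np.array([10.0, 100.0, 200.0]), np.array([10.1, 100.1, 200.1])],
            n_cells=2, analyzed_duration=360.0))
        assert ca.gdp_frequency(gdps, 360.0) == pytest.approx(0.5)

    def test_planted_gdps_recovered(self):
        traces, truth = synth.gen_calcium(make_config("calcium", 480.0, 10.0, 8))
        out = ca.compute_dff(traces.F, traces.frame_times)
        raster = ca.detect_cats(out)
        gdps = ca.detect_gdps(raster)
        planted = truth.event_times["gdp"]
        starts = np.array([g.start for g in gdps])
        tp, miss, _ = match_events(starts, planted, tol_s=0.6)
        assert miss <= max(1, int(0.1 * len(planted)))
        assert abs(len(gdps) - len(planted)) <= max(2, int(0.25 * len(planted)))

    def test_invalid_fraction(self):
        raster = CaTRaster(onsets=[np.array([1.0])], n_cells=1,
                           analyzed_duration=10.0)
        with pytest.raises(ValueError):
            ca.detect_gdps(raster, fraction=0.0)
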