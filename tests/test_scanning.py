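"""Scanning, z-profiles, the cut-off grid and functional-window detection."""

import numpy as np
import pytest

from pwmrefine.formats_io import PromoterSet
from pwmrefine.pwm_model import ScoringModel, build_mono_pwm, score
from pwmrefine.scanning import (
    CutoffGrid,
    FunctionalWindow,
    cutoff_z_grid,
    default_cutoff_grid,
    detect_functional_windows,
    scan,
    score_all_windows,
    z_profile,
    _profile_from_counts,
)
from pwmrefine.synthetic import generate_promoters

from .conftest import random_sites


def brute_force_scan(model, promoters, window=None):
    """Independent rescan of every window with the scalar scorer."""
    L = model.matrix.L
    lo = 0 if window is None else window.start
    hi = promoters.length - L if window is None else window.end - L
    hits = set()
    for pid, seq in zip(promoters.identifiers, promoters.sequences):
        for start in range(lo, hi + 1):
            if score(model.matrix, seq[start:start + L]) >= model.cutoff:
                hits.add((pid, start))
    return hits


class TestScan:
    def test_matches_brute_force_oracle(self, rng, uniform_background):
        promoters = generate_promoters(20, 80, seed=7, tss_offset=0)
        sites = random_sites(rng, 6, 6)
        pwm = build_mono_pwm(sites, uniform_background)
        for cutoff in (0.0, -2.0, -5.0):
            model = ScoringModel(pwm, cutoff)
            assert scan(model, promoters).pairs() == brute_force_scan(model, promoters)

    def test_cutoff_zero_finds_only_score_zero_windows(self, rng, uniform_background):
        # only windows realizing the per-column maximum everywhere (the
        # consensus, or its ties) qualify at cutoff 0
        promoters = generate_promoters(10, 60, seed=9, tss_offset=0)
        pwm = build_mono_pwm(random_sites(rng, 5, 5), uniform_background)
        hits = scan(ScoringModel(pwm, 0.0), promoters)
        from pwmrefine.pwm_model import score

        for pid, start in hits.pairs():
            seq = promoters.sequences[promoters.identifiers.index(pid)]
            assert score(pwm, seq[start:start + 5]) == 0.0

    def test_unbounded_cutoff_hits_every_position(self, rng, uniform_background):
        promoters = generate_promoters(5, 30, seed=1, tss_offset=0)
        pwm = build_mono_pwm(random_sites(rng, 5, 5), uniform_background)
        hits = scan(ScoringModel(pwm, -np.inf), promoters)
        assert len(hits) == 5 * (30 - 5 + 1)

    def test_window_restriction(self, rng, uniform_background):
        promoters = generate_promoters(8, 50, seed=2, tss_offset=0)
        pwm = build_mono_pwm(random_sites(rng, 5, 5), uniform_background)
        window = FunctionalWindow(start=10, end=20, peak_z=5.0)
        hits = scan(ScoringModel(pwm, -np.inf), promoters, window)
        starts = {s for _, s in hits.pairs()}
        assert starts == set(range(10, 16))  # starts whose motif fits in [10, 20)

    def test_window_shorter_than_motif_rejected(self, rng, uniform_background):
        promoters = generate_promoters(3, 30, seed=3, tss_offset=0)
        pwm = build_mono_pwm(random_sites(rng, 5, 6), uniform_background)
        with pytest.raises(ValueError):
            scan(ScoringModel(pwm, 0.0), promoters,
                 FunctionalWindow(start=4, end=8, peak_z=3.0))


class TestZProfile:
    def test_constant_counts_give_zero_z(self):
        profile = _profile_from_counts(np.full(10, 7.0), cutoff=-1.0)
        assert profile.sigma == 0.0
        assert np.all(profile.z == 0.0)

    def test_single_peak_toy_population_sd(self):
        profile = _profile_from_counts(np.array([0, 0, 10, 0, 0], dtype=float), 0.0)
        assert profile.E == pytest.approx(2.0)
        assert profile.sigma == pytest.approx(4.0)
        assert profile.z.max() == pytest.approx(2.0)

    def test_profile_length_matches_scan_positions(self, rng, uniform_background):
        promoters = generate_promoters(10, 70, seed=4, tss_offset=0)
        pwm = build_mono_pwm(random_sites(rng, 5, 6), uniform_background)
        profile = z_profile(ScoringModel(pwm, -3.0), promoters)
        assert len(profile.O) == 70 - 6 + 1
        assert np.allclose(profile.z * profile.sigma + profile.E, profile.O)

    def test_no_planted_motif_rarely_exceeds_threshold(self, rng, uniform_background):
        # i.i.d. promoters with no planted signal: |z| >= 3 is rare
        promoters = generate_promoters(50, 1005, seed=5, tss_offset=0)
        pwm = build_mono_pwm(random_sites(rng, 8, 6), uniform_background)
        profile = z_profile(ScoringModel(pwm, -4.0), promoters)
        assert (np.abs(profile.z) >= 3).mean() < 0.05


class TestCutoffGrid:
    def test_single_cutoff_grid_reduces_to_z_profile(self, rng, uniform_background):
        promoters = generate_promoters(10, 60, seed=6, tss_offset=0)
        pwm = build_mono_pwm(random_sites(rng, 5, 5), uniform_background)
        grid = cutoff_z_grid(pwm, promoters, np.array([-2.0]))
        profile = z_profile(ScoringModel(pwm, -2.0), promoters)
        assert np.allclose(grid.z[0], profile.z)

    def test_raising_cutoff_never_increases_counts(self, rng, uniform_background):
        promoters = generate_promoters(15, 80, seed=8, tss_offset=0)
        pwm = build_mono_pwm(random_sites(rng, 6, 6), uniform_background)
        grid = cutoff_z_grid(pwm, promoters)  # descending: stringent -> permissive
        assert (np.diff(grid.O, axis=0) >= 0).all()

    def test_default_grid_spans_score_range(self, rng, uniform_background):
        pwm = build_mono_pwm(random_sites(rng, 5, 6), uniform_background)
        grid = default_cutoff_grid(pwm)
        assert grid[0] == 0.0
        assert grid[-1] <= pwm.min_score()
        assert np.allclose(np.diff(grid), -0.5)

    def test_positive_cutoffs_rejected(self, rng, uniform_background, small_promoters):
        pwm = build_mono_pwm(random_sites(rng, 5, 6), uniform_background)
        with pytest.raises(ValueError):
            cutoff_z_grid(pwm, small_promoters, np.array([0.5]))

    def test_planted_peak_column_stable_across_cutoffs(self, uniform_background):
        # a fixture with an invariant motif planted at one offset: the peak
        # column is identical for every cutoff that retains at least 1 hit
        rng = np.random.default_rng(12)
        motif = "ACGTAC"
        seqs = []
        for _ in range(30):
            s = "".join(np.array(list("ATGC"))[rng.integers(0, 4, 60)])
            seqs.append(s[:20] + motif + s[26:])
        promoters = PromoterSet(seqs, tss_offset=0)
        pwm = build_mono_pwm((__import__("pwmrefine").SiteSet)([motif] * 5),
                             uniform_background)
        grid = cutoff_z_grid(pwm, promoters, np.array([0.0, -0.5, -1.0]))
        peaks = grid.z.argmax(axis=1)
        assert set(peaks.tolist()) == {20}


class TestWindowDetection:
    @staticmethod
    def _grid_from_z(z_rows, cutoffs):
        z = np.array(z_rows, dtype=float)
        return CutoffGrid(cutoffs=np.array(cutoffs), z=z, O=np.zeros_like(z))

    def test_nearby_peaks_fuse_into_one_window(self):
        # peaks at 515-516 and 519-520 with motif length 13: distance 3 < 13
        z = np.zeros(530)
        z[[515, 516, 519, 520]] = 4.0
        grid = self._grid_from_z([z], [-1.0])
        windows = detect_functional_windows(grid, L=13)
        assert len(windows) == 1
        assert windows[0].start == 515
        assert windows[0].end == 520 + 13

    def test_distant_peaks_stay_separate(self):
        z = np.zeros(100)
        z[[10, 30]] = 5.0  # separation 20 = 2 L
        grid = self._grid_from_z([z], [-1.0])
        windows = detect_functional_windows(grid, L=10)
        assert len(windows) == 2

    def test_all_below_threshold_gives_empty_list(self):
        grid = self._grid_from_z([np.full(50, 2.9)], [-1.0])
        assert detect_functional_windows(grid, L=8) == []

    def test_single_peak_window_has_span_L(self):
        z = np.zeros(60)
        z[25] = 6.0
        grid = self._grid_from_z([z], [-2.0])
        (window,) = detect_functional_windows(grid, L=8)
        assert (window.start, window.end) == (25, 33)
        assert window.span == 8

    def test_cutoff_band_is_contiguous_run_around_peak_row(self):
        z1 = np.zeros(40); z1[20] = 4.0
        z2 = np.zeros(40); z2[20] = 6.0
        z3 = np.zeros(40)          # signal gone
        z4 = np.zeros(40); z4[35] = 3.5  # unrelated noise deeper down
        grid = self._grid_from_z([z1, z2, z3, z4], [0.0, -0.5, -1.0, -1.5])
        windows = detect_functional_windows(grid, L=6)
        main = windows[0]
        assert main.peak_z == 6.0
        assert main.cutoff_range == (0.0, -0.5)

    def test_windows_sorted_strongest_first(self):
        z = np.zeros(100)
        z[10] = 3.5
        z[60] = 8.0
        grid = self._grid_from_z([z], [-1.0])
        windows = detect_functional_windows(grid, L=8)
        assert windows[0].start == 60


def test_score_all_windows_agrees_with_scalar_scorer(rng, uniform_background):
    promoters = generate_promoters(6, 40, seed=10, tss_offset=0)
    pwm = build_mono_pwm(random_sites(rng, 5, 6), uniform_background)
    matrix = score_all_windows(pwm, promoters)
    for i, seq in enumerate(promoters.sequences):
        for p in range(40 - 6 + 1):
            assert matrix[i, p] == pytest.approx(score(pwm, seq[p:p + 6]))
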