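"""Banded alignment, window statistics, response table, loess and model fit."""

import numpy as np
import pytest

from anccap import windows as win
from anccap.windows import (
    WindowParams,
    WindowStat,
    align_banded,
    divergence_response,
    fit_capture_model,
    loess_trend,
    window_depth,
    window_identity,
)

from conftest import make_read, random_reads


def affine_dp_score(a, b, match=1.0, mis=-1.0, go=-5.0, ge=-1.0):
    """Unbanded Gotoh global alignment score (oracle; gap cost go + g*ge)."""
    NEG = -1e30
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + ge * i
    for j in range(1, m + 1):
        Y[0][j] = go + ge * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mis
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + go + ge, X[i - 1][j] + ge)
            Y[i][j] = max(M[i][j - 1] + go + ge, Y[i][j - 1] + ge)
    return max(M[n][m], X[n][m], Y[n][m])


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignBanded:
    def test_identical_sequences(self):
        rng = np.random.default_rng(70)
        s = _rand_seq(rng, 300)
        aln = align_banded(s, s)
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_a + aln.aligned_b
        assert aln.score == 300.0

    def test_single_mismatch_identity(self):
        aln = align_banded("ACGT", "ACGA", band_width=10)
        assert aln.identity == 0.75

    def test_gap_rows_restore_inputs(self):
        rng = np.random.default_rng(71)
        s = _rand_seq(rng, 200)
        t = s[:80] + s[90:]  # 10 bp deletion
        aln = align_banded(s, t, band_width=50)
        assert aln.aligned_a.replace("-", "") == s
        assert aln.aligned_b.replace("-", "") == t
        assert len(aln.aligned_a) == len(aln.aligned_b)

    def test_matches_unbanded_oracle_500bp(self):
        rng = np.random.default_rng(72)
        s = list(_rand_seq(rng, 500))
        t = list(s)
        for _ in range(40):  # substitutions
            t[rng.integers(0, len(t))] = rng.choice(list("ACGT"))
        for _ in range(3):  # small indels
            p = int(rng.integers(0, len(t) - 3))
            del t[p : p + int(rng.integers(1, 4))]
        s, t = "".join(s), "".join(t)
        assert align_banded(s, t, band_width=40).score == pytest.approx(affine_dp_score(s, t))

    def test_length_difference_beyond_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            align_banded("A" * 100, "A" * 350, band_width=200)

    def test_band_widens_with_warning(self):
        # a 20 bp insertion paired with a 10 bp deletion needs a 20-column
        # path excursion; band 13 must auto-widen to recover the optimum
        rng = np.random.default_rng(73)
        x, y, z, ins = (_rand_seq(rng, n) for n in (60, 60, 60, 20))
        s = x + y + z
        t = x + ins + y + z[:50]
        with pytest.warns(UserWarning, match="band"):
            aln = align_banded(s, t, band_width=13)
        assert aln.score == pytest.approx(affine_dp_score(s, t))

    def test_terminal_gaps_excluded_from_identity(self):
        aln = align_banded("AAAATTTT", "TTTT", band_width=7)
        # best alignment places TTTT against the tail; leading gap columns
        # must not count toward identity
        assert aln.identity == 1.0


class TestWindowIdentity:
    def test_window_count_region_150(self):
        a = "A" * 200
        wins = window_identity(a, a, WindowParams(window=60, step=30, region=(0, 150)))
        assert [w.start for w in wins] == [0, 30, 60, 90]

    def test_identical_rows_identity_one(self):
        a = "ACGT" * 100
        wins = window_identity(a, a, WindowParams(window=60, step=30, region=(0, 400)))
        assert all(w.identity == 1.0 for w in wins)
        assert not any(w.has_gap for w in wins)

    def test_six_mismatches_in_window(self):
        a = "A" * 120
        b = "A" * 120
        b = b[:10] + "C" * 6 + b[16:]
        wins = window_identity(a, b, WindowParams(window=60, step=60, region=(0, 120)))
        assert wins[0].identity == pytest.approx(0.90)
        assert wins[1].identity == 1.0

    def test_gap_and_n_flagging(self):
        a = "A" * 60 + "A" * 60
        b = "A" * 30 + "-" + "A" * 29 + "A" * 25 + "N" + "A" * 34
        wins = window_identity(a, b, WindowParams(window=60, step=60, region=(0, 120)))
        assert [w.has_gap for w in wins] == [True, True]
        # identity computed over remaining comparable columns
        assert wins[0].identity == pytest.approx(1.0)

    def test_window_count_formula_matches_enumeration(self):
        """floor((region - window)/step) + 1 windows, checked against brute
        enumeration over 100 random geometries."""
        rng = np.random.default_rng(74)
        for _ in range(100):
            length = int(rng.integers(80, 400))
            window = int(rng.integers(10, 70))
            step = int(rng.integers(1, window + 1))
            lo = int(rng.integers(0, length - window))
            hi = int(rng.integers(lo + window, length + 1))
            wins = window_identity("A" * length, "A" * length,
                                   WindowParams(window=window, step=step, region=(lo, hi)))
            brute = [s for s in range(lo, hi + 1, step) if s + window <= hi]
            assert len(wins) == (hi - lo - window) // step + 1 == len(brute)

    def test_recovers_divergence_track(self, study):
        """Mean window divergence per segment lands within 3 binomial SD of
        the generating target."""
        track = study["track"]
        wins = study["windows"]
        for start, end, d in track.segments:
            inside = [w for w in wins if w.start >= start and w.end <= end]
            if len(inside) < 10:
                continue
            n_sites = sum(w.end - w.start for w in inside) / 2  # windows overlap by half
            observed = np.mean([w.divergence for w in inside])
            sd = np.sqrt(max(d * (1 - d), 1e-4) / n_sites)
            assert abs(observed - d) < 3 * sd + 1e-9

    def test_region_outside_alignment_rejected(self):
        with pytest.raises(ValueError):
            window_identity("A" * 100, "A" * 100, WindowParams(region=(0, 200)))


class TestWindowDepth:
    def test_no_reads_zero_depth(self):
        wins = [WindowStat(0, 60, 1.0), WindowStat(30, 90, 1.0)]
        window_depth([], wins, 100, which="capture")
        assert all(w.depth_capture == 0.0 for w in wins)

    def test_single_covering_read(self):
        wins = [WindowStat(0, 60, 1.0), WindowStat(30, 90, 1.0)]
        window_depth([make_read(0, 60)], wins, 100, which="capture")
        assert wins[0].depth_capture == 1.0
        assert wins[1].depth_capture == 0.5  # 30 of 60 positions covered

    def test_matches_per_position_oracle(self):
        rng = np.random.default_rng(75)
        reads = random_reads(rng, 300, 500)
        wins = [WindowStat(s, s + 60, 1.0) for s in range(0, 440, 30)]
        window_depth(reads, wins, 500, which="shotgun")
        depth = np.zeros(500)
        for r in reads:
            depth[r.start : r.end] += 1
        for w in wins:
            assert w.depth_shotgun == pytest.approx(depth[w.start : w.end].mean())


class TestDivergenceResponse:
    def test_single_bin_proportion_one(self):
        wins = [WindowStat(s, s + 60, 0.95, 2.0, 2.0) for s in range(0, 300, 30)]
        table = divergence_response(wins, WindowParams(region=(0, 360)))
        assert len(table) == 1
        assert table["prop_windows"].iloc[0] == 1.0

    def test_neutral_capture_ratio_one(self):
        rng = np.random.default_rng(76)
        wins = [
            WindowStat(30 * i, 30 * i + 60, float(ident), d, d)
            for i, (ident, d) in enumerate(zip(rng.uniform(0.7, 1.0, 50), rng.uniform(1, 9, 50)))
        ]
        table = divergence_response(wins, WindowParams(region=(0, 10000)))
        assert np.allclose(table["ratio"].dropna(), 1.0)

    def test_proportions_sum_to_one(self, study):
        table = divergence_response(study["windows"], study["window_params"])
        assert table["prop_windows"].sum() == pytest.approx(1.0)
        assert table["prop_capture"].sum() == pytest.approx(1.0)
        assert table["prop_shotgun"].sum() == pytest.approx(1.0)

    def test_gap_windows_excluded_and_all_gaps_rejected(self):
        wins = [WindowStat(0, 60, 0.9, 1.0, 1.0, has_gap=True)]
        with pytest.raises(ValueError):
            divergence_response(wins, WindowParams(region=(0, 600)))

    def test_capture_bias_profile(self, study):
        """The end-to-end contrast: capture overrepresents the most similar
        windows and deserts windows beyond the retention midpoint."""
        table = divergence_response(study["windows"], study["window_params"])
        first = table.iloc[0]
        assert first["bin_low"] == 0.0
        assert first["prop_capture"] > first["prop_shotgun"]
        high = table[table["bin_low"] >= 0.22].dropna(subset=["ratio"])
        assert (high["prop_capture"] < high["prop_shotgun"]).all()

    def test_ratio_non_increasing(self, study):
        table = divergence_response(study["windows"], study["window_params"])
        r = table["ratio"].dropna().to_numpy()
        assert np.all(np.diff(r) <= 0.05)


class TestLoess:
    def test_exact_on_collinear_input(self):
        x = np.linspace(0, 1, 40)
        y = 2 * x + 1
        grid, fitted = loess_trend(x, y, span=0.5, grid=x)
        assert np.allclose(fitted, y, atol=1e-9)

    def test_constant_input_constant_fit(self):
        x = np.linspace(0, 1, 30)
        grid, fitted = loess_trend(x, np.full(30, 3.5))
        assert np.allclose(fitted, 3.5)

    def test_monotone_fit_on_noisy_logistic(self):
        rng = np.random.default_rng(77)
        x = np.sort(rng.uniform(0, 1, 200))
        y = 1 / (1 + np.exp(10 * (x - 0.5))) + rng.normal(0, 0.02, 200)
        grid, fitted = loess_trend(x, y, span=0.5)
        assert np.all(np.diff(fitted) <= 1e-6)

    def test_agrees_with_statsmodels_lowess(self):
        """Cross-check against the reference tricube local-linear smoother."""
        import statsmodels.api as sm

        rng = np.random.default_rng(78)
        x = np.sort(rng.uniform(0, 1, 80))
        y = np.sin(3 * x) + rng.normal(0, 0.05, 80)
        _, ours = loess_trend(x, y, span=0.4, grid=x)
        theirs = sm.nonparametric.lowess(y, x, frac=0.4, it=0, return_sorted=False)
        assert np.corrcoef(ours, theirs)[0, 1] > 0.999
        assert np.max(np.abs(ours - theirs)) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_trend(np.arange(4), np.arange(4))


class TestFitCaptureModel:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(79)
        ident = rng.uniform(0.7, 1.0, 200)
        ratio = 1.3 / (1 + np.exp(-40 * (ident - 0.80)))
        wins = [WindowStat(30 * i, 30 * i + 60, float(p), float(r), 1.0)
                for i, (p, r) in enumerate(zip(ident, ratio))]
        fit = fit_capture_model(wins, n_boot=0)
        assert fit.id_50 == pytest.approx(0.80, abs=1e-6)
        assert fit.slope == pytest.approx(40.0, abs=1e-4)
        assert fit.amplitude == pytest.approx(1.3, abs=1e-6)

    def test_flat_ratio_rejected(self):
        wins = [WindowStat(30 * i, 30 * i + 60, 0.7 + 0.001 * i, 2.0, 1.0) for i in range(100)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_capture_model(wins)

    def test_degenerate_divergence_spread_rejected(self):
        wins = [WindowStat(30 * i, 30 * i + 60, 0.9, float(i % 7), 1.0) for i in range(50)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_capture_model(wins)

    def test_bootstrap_interval_covers_truth(self, study):
        fit = fit_capture_model(study["windows"], n_boot=200, seed=80)
        lo, hi = fit.ci_id_50
        assert lo <= study["capture_model"].id_50 <= hi
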