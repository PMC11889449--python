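import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabomix import (
    PeakError,
    ShiftContext,
    SpectrumGrid1D,
    SpectrumGrid2D,
    apply_shift_1d,
    apply_shift_2d,
    compute_delta_shift,
    detect_peaks_1d,
    diagonal_projection,
    sample_pka,
    skyline_projection,
)


def brute_force_clusters(y, main_frac, cluster_frac):
    """Independent exhaustive run-scan oracle for the two-threshold rule."""
    y = np.asarray(y, dtype=float)
    top = y.max(initial=0.0)
    if top <= 0:
        return []
    main_abs, cluster_abs = main_frac * top, cluster_frac * top
    out = []
    n = len(y)
    for s in range(n):
        for e in range(s + 1, n + 1):
            run = all(y[i] >= cluster_abs for i in range(s, e))
            maximal = run and (s == 0 or y[s - 1] < cluster_abs) and (e == n or y[e] < cluster_abs)
            if not maximal:
                continue
            apexes = [
                k
                for k in range(s, e)
                if y[k] >= main_abs
                and y[k] >= (y[k - 1] if k > 0 else -np.inf)
                and y[k] > (y[k + 1] if k + 1 < n else -np.inf)
            ]
            if apexes:
                out.append(((s, e), apexes))
    return out


def _axis(n):
    return np.linspace(10.0, 0.0, n)


class TestDetect:
    def test_hand_worked_vector(self):
        y = np.array([0, 1, 5, 1, 0, 0, 2, 2, 0], dtype=float)
        cs = detect_peaks_1d(SpectrumGrid1D(_axis(9), y), 0.6, 0.15)
        assert cs.clusters == [(1, 4)]
        assert cs.apexes == [[2]]

    def test_all_zero_empty(self):
        cs = detect_peaks_1d(SpectrumGrid1D(_axis(16), np.zeros(16)), 0.5, 0.1)
        assert len(cs) == 0

    def test_single_lorentzian_one_cluster(self, axis):
        hw = 0.005
        y = hw / ((axis - 3.0) ** 2 + hw**2)
        cs = detect_peaks_1d(SpectrumGrid1D(axis, y), 0.5, 0.1)
        assert len(cs) == 1
        assert len(cs.apexes[0]) == 1
        apex_ppm = axis[cs.apexes[0][0]]
        assert apex_ppm == pytest.approx(3.0, abs=2 * (axis[0] - axis[1]))

    def test_bad_thresholds_rejected(self):
        with pytest.raises(PeakError):
            detect_peaks_1d(SpectrumGrid1D(_axis(8), np.ones(8)), 0.1, 0.5)

    def test_agrees_with_oracle_random(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 200))
            y = rng.random(n) * rng.choice([0.0, 1.0, 10.0])
            main = float(rng.uniform(0.3, 1.0))
            cluster = float(rng.uniform(0.01, main))
            cs = detect_peaks_1d(SpectrumGrid1D(_axis(n), y), main, cluster)
            expected = brute_force_clusters(y, main, cluster)
            assert list(zip(cs.clusters, cs.apexes)) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        y=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=60),
        main=st.floats(0.2, 1.0),
        frac=st.floats(0.05, 1.0),
    )
    def test_oracle_property(self, y, main, frac):
        cluster = main * frac
        cs = detect_peaks_1d(SpectrumGrid1D(_axis(len(y)), np.array(y)), main, cluster)
        assert list(zip(cs.clusters, cs.apexes)) == brute_force_clusters(y, main, cluster)


class TestProjections:
    def test_skyline_column_maxima(self):
        g = SpectrumGrid2D(
            f2_axis=np.array([2.0, 1.0]),
            f1_axis=np.array([-1.0, 1.0]),
            intensity=np.array([[1.0, 0.0], [0.0, 2.0]]),
            mode="jres",
        )
        assert np.array_equal(skyline_projection(g).intensity, [1.0, 2.0])

    def test_skyline_matches_bruteforce_random(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.random((int(rng.integers(2, 20)), int(rng.integers(2, 20))))
            g = SpectrumGrid2D(
                np.linspace(9, 0, m.shape[1]), np.linspace(-20, 20, m.shape[0]), m, "jres"
            )
            expected = [max(m[i][j] for i in range(m.shape[0])) for j in range(m.shape[1])]
            assert np.array_equal(skyline_projection(g).intensity, expected)

    def test_diagonal_trace(self):
        ax = np.array([3.0, 2.0, 1.0])
        m = np.diag([3.0, 1.0, 4.0])
        g = SpectrumGrid2D(ax, ax, m, "cosy")
        assert np.array_equal(diagonal_projection(g).intensity, [3.0, 1.0, 4.0])

    def test_diagonal_matches_bruteforce_random(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            m = rng.random((n, n))
            ax = np.linspace(9, 0, n)
            g = SpectrumGrid2D(ax, ax, m, "cosy")
            assert np.array_equal(
                diagonal_projection(g).intensity, [m[i][i] for i in range(n)]
            )

    def test_cross_peak_only_matrix_projects_to_zero(self):
        ax = np.linspace(5, 1, 8)
        m = np.ones((8, 8)) - np.eye(8)
        m[np.arange(8), np.arange(8)] = 0.0
        g = SpectrumGrid2D(ax, ax, m, "cosy")
        assert np.all(diagonal_projection(g).intensity == 0.0)

    def test_mode_mismatch_rejected(self):
        ax = np.linspace(5, 1, 4)
        g = SpectrumGrid2D(ax, ax, np.zeros((4, 4)), "cosy")
        with pytest.raises(PeakError):
            skyline_projection(g)


class TestDeltaShift:
    def test_equal_ph_zero_shift(self):
        assert compute_delta_shift(3.0, 2.8, 7.0, 7.4, 7.4) == 0.0

    def test_worked_scalar_case(self):
        # independent direct evaluation of the Henderson-Hasselbalch form
        dl, dhl, pka, ph0, ph1 = 3.00, 2.80, 7.0, 7.4, 6.5
        direct = (
            (dl - dhl)
            * (10 ** (ph0 - pka) - 10 ** (ph1 - pka))
            / ((1 + 10 ** (ph0 - pka)) * (1 + 10 ** (ph1 - pka)))
        )
        assert compute_delta_shift(dl, dhl, pka, ph0, ph1) == pytest.approx(direct, abs=1e-12)
        assert direct == pytest.approx(0.0950, abs=5e-5)

    def test_full_traversal_limit(self):
        shift = compute_delta_shift(3.0, 2.8, 7.0, 2.0, 12.0)
        assert shift == pytest.approx(-0.2, abs=1e-4)

    def test_overflow_safe_extremes(self):
        assert np.isfinite(compute_delta_shift(3.0, 2.8, 7.0, -500.0, 500.0))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        dl=st.floats(-10, 10),
        dhl=st.floats(-10, 10),
        pka=st.floats(0, 14),
        ph0=st.floats(0, 14),
        ph1=st.floats(0, 14),
    )
    def test_bound_and_antisymmetry(self, dl, dhl, pka, ph0, ph1):
        d = compute_delta_shift(dl, dhl, pka, ph0, ph1)
        assert abs(d) <= abs(dl - dhl) + 1e-12
        assert d == pytest.approx(-compute_delta_shift(dl, dhl, pka, ph1, ph0), abs=1e-12)

    def test_monotone_decreasing_in_sample_ph(self):
        ph1_grid = np.linspace(2.0, 12.0, 101)
        shifts = [compute_delta_shift(3.0, 2.8, 7.0, 7.4, p) for p in ph1_grid]
        assert np.all(np.diff(shifts) < 0)


class TestSamplePka:
    def test_degenerate_sd(self):
        ctx = ShiftContext(pka_fallback_mean=6.8, pka_fallback_sd=0.0)
        assert sample_pka(ctx, 0) == 6.8

    def test_monte_carlo_mean(self):
        ctx = ShiftContext(pka_fallback_mean=7.0, pka_fallback_sd=1.0)
        rng = np.random.default_rng(0)
        draws = [sample_pka(ctx, rng) for _ in range(10**4)]
        assert np.mean(draws) == pytest.approx(7.0, abs=0.05)

    def test_clamped_to_ph_scale(self):
        ctx = ShiftContext(pka_fallback_mean=15.0, pka_fallback_sd=0.0)
        assert sample_pka(ctx, 0) == 14.0


def _toy_cluster_spectrum():
    axis = _axis(100)
    y = np.zeros(100)
    y[40:45] = [1.0, 3.0, 5.0, 3.0, 1.0]
    spec = SpectrumGrid1D(axis, y)
    cs = detect_peaks_1d(spec, 0.5, 0.1)
    assert cs.clusters == [(40, 45)]
    return spec, cs


class TestShift1D:
    def test_zero_shift_identity(self):
        spec, cs = _toy_cluster_spectrum()
        out = apply_shift_1d(spec, cs, [0.0])
        assert np.array_equal(out.intensity, spec.intensity)

    def test_positive_shift_moves_toward_higher_ppm(self):
        spec, cs = _toy_cluster_spectrum()
        d = 10 * spec.spacing
        out = apply_shift_1d(spec, cs, [d])
        # apex at 42 moves to 32 (descending axis: higher ppm = lower index)
        assert np.argmax(out.intensity) == 32
        assert out.integral() == pytest.approx(spec.integral(), rel=1e-9)

    def test_collision_detected(self):
        axis = _axis(60)
        y = np.zeros(60)
        y[10:13] = [2.0, 5.0, 2.0]
        y[20:23] = [2.0, 5.0, 2.0]
        spec = SpectrumGrid1D(axis, y)
        cs = detect_peaks_1d(spec, 0.5, 0.1)
        assert len(cs) == 2
        shifts = [-5 * spec.spacing, 5 * spec.spacing]  # both move to ~index 15
        with pytest.raises(PeakError, match="collides"):
            apply_shift_1d(spec, cs, shifts)
        out = apply_shift_1d(spec, cs, shifts, collision="sum")
        assert out.integral() == pytest.approx(spec.integral(), rel=1e-9)

    def test_fully_off_grid_rejected(self):
        spec, cs = _toy_cluster_spectrum()
        with pytest.raises(PeakError, match="off the grid"):
            apply_shift_1d(spec, cs, [200 * spec.spacing])


def _jres_fixture():
    from metabomix import MultipletSpec, ToyMetaboliteSpec, make_pure_jres

    spec = ToyMetaboliteSpec(
        id="t",
        name="t",
        protons=2,
        multiplets=(MultipletSpec(center=3.0, pattern="d", j_hz=7.0, protons_weight=2.0),),
    )
    axis = np.linspace(9.995, -0.005, 1024)
    return make_pure_jres(spec, axis, np.linspace(-30, 30, 121))


class TestShift2D:
    def test_zero_shift_identity(self):
        g = _jres_fixture()
        proj = skyline_projection(g)
        cs = detect_peaks_1d(proj, 0.5, 0.05)
        out = apply_shift_2d(g, cs, [0.0] * len(cs))
        assert np.array_equal(out.intensity, g.intensity)

    def test_projection_shift_commutation(self):
        g = _jres_fixture()
        proj = skyline_projection(g)
        cs = detect_peaks_1d(proj, 0.5, 0.05)
        spacing = proj.spacing
        shifts = [17 * spacing] * len(cs)
        a = skyline_projection(apply_shift_2d(g, cs, shifts)).intensity
        b = apply_shift_1d(proj, cs, shifts).intensity
        assert np.array_equal(a, b)

    def test_jres_shift_preserves_f1_structure(self):
        g = _jres_fixture()
        proj = skyline_projection(g)
        cs = detect_peaks_1d(proj, 0.5, 0.05)
        shift = 0.1  # ppm
        out = apply_shift_2d(g, cs, [shift] * len(cs))
        # the apex column moves by the shift...
        col0 = int(np.argmax(g.intensity.max(axis=0)))
        col1 = int(np.argmax(out.intensity.max(axis=0)))
        d_ppm = g.f2_axis[col1] - g.f2_axis[col0]
        assert d_ppm == pytest.approx(shift, abs=2 * abs(g.f2_axis[1] - g.f2_axis[0]))
        # ...while the F1 doublet offsets (+-J/2) are untouched
        def f1_apexes(mat, col):
            trace = mat[:, col]
            return sorted(g.f1_axis[i] for i in np.argsort(trace)[-2:])

        assert f1_apexes(out.intensity, col1) == f1_apexes(g.intensity, col0)
        assert np.allclose(f1_apexes(g.intensity, col0), [-3.5, 3.5], atol=0.5)
        assert out.intensity.sum() == pytest.approx(g.intensity.sum(), rel=1e-9)

    def test_cosy_diagonal_shift_keeps_symmetry(self, axis_2d):
        from metabomix import MultipletSpec, ToyMetaboliteSpec, make_pure_cosy

        spec = ToyMetaboliteSpec(
            id="t",
            name="t",
            protons=2,
            multiplets=(
                MultipletSpec(center=2.0, protons_weight=1.0),
                MultipletSpec(center=7.0, protons_weight=1.0),
            ),
        )
        g = make_pure_cosy(spec, axis_2d, coupled_pairs=[(0, 1)])
        proj = diagonal_projection(g)
        cs = detect_peaks_1d(proj, 0.5, 0.05)
        assert len(cs) == 2
        out = apply_shift_2d(g, cs, [0.05, -0.08])
        assert out.is_symmetric(tol=1e-9)
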