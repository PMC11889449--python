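import numpy as np
import pytest

from metabomix import (
    ConditionStats,
    ContinuousDesign,
    DiscreteDesign,
    GroupSpec,
    MetaboliteResponse,
    MixtureError,
    MixtureSpec,
    add_noise,
    add_protein_background,
    simulate_cohort,
    simulate_mixture_1d,
    simulate_mixture_2d,
)


class TestMixture1D:
    def test_single_metabolite_identity(self, toy_library):
        mid = toy_library.ids()[0]
        s = simulate_mixture_1d(toy_library, {mid: 1.0}, MixtureSpec())
        assert np.array_equal(s.grid.intensity, toy_library[mid].spectrum_1d.intensity)

    def test_homogeneity(self, toy_library):
        mid = toy_library.ids()[0]
        s1 = simulate_mixture_1d(toy_library, {mid: 1.0}, MixtureSpec())
        s2 = simulate_mixture_1d(toy_library, {mid: 2.0}, MixtureSpec())
        assert np.array_equal(s2.grid.intensity, 2.0 * s1.grid.intensity)

    def test_superposition(self, toy_library):
        ids = toy_library.ids()
        conc = {m: float(i + 1) for i, m in enumerate(ids)}
        joint = simulate_mixture_1d(toy_library, conc, MixtureSpec())
        total = np.zeros_like(joint.grid.intensity)
        for m, c in conc.items():
            total += simulate_mixture_1d(toy_library, {m: c}, MixtureSpec()).grid.intensity
        assert np.allclose(joint.grid.intensity, total, rtol=1e-12, atol=1e-12 * total.max())

    def test_unknown_id_rejected(self, toy_library):
        with pytest.raises(Exception, match="zz"):
            simulate_mixture_1d(toy_library, {"zz": 1.0}, MixtureSpec())

    def test_negative_concentration_rejected(self, toy_library):
        mid = toy_library.ids()[0]
        with pytest.raises(MixtureError, match="negative"):
            simulate_mixture_1d(toy_library, {mid: -1.0}, MixtureSpec())

    def test_provenance_records_concentrations(self, toy_library):
        conc = {m: 2.5 for m in toy_library.ids()}
        s = simulate_mixture_1d(toy_library, conc, MixtureSpec())
        assert s.concentrations == conc


class TestProteinBackground:
    def test_scale_zero_identity(self, blood_library):
        mid = blood_library.ids()[0]
        s0 = simulate_mixture_1d(blood_library, {mid: 1.0}, MixtureSpec(protein_scale=0.0))
        assert np.array_equal(s0.grid.intensity, blood_library[mid].spectrum_1d.intensity)

    def test_zero_signal_gives_background(self, blood_library):
        mid = blood_library.ids()[0]
        s = simulate_mixture_1d(blood_library, {mid: 0.0}, MixtureSpec(protein_scale=1.0))
        assert np.array_equal(s.grid.intensity, blood_library.protein_background.intensity)

    def test_integral_additivity(self, blood_library):
        mid = blood_library.ids()[0]
        base = blood_library[mid].spectrum_1d
        out = add_protein_background(base, blood_library.protein_background, 3.0)
        expected = base.integral() + 3.0 * blood_library.protein_background.integral()
        assert out.integral() == pytest.approx(expected, rel=1e-9)

    def test_grid_mismatch_rejected(self, blood_library):
        from metabomix import SpectrumGrid1D

        other = SpectrumGrid1D(np.linspace(5.0, 0.0, 64), np.ones(64))
        with pytest.raises(MixtureError):
            add_protein_background(other, blood_library.protein_background, 1.0)

    def test_baseline_integral_monotone_in_scale(self, blood_library):
        conc = {m: 100.0 for m in blood_library.ids()}
        axis = blood_library.common_grid
        sel = (axis >= 0.5) & (axis <= 3.0)
        integrals = []
        for scale in (0.0, 0.5, 1.0, 2.0, 4.0):
            s = simulate_mixture_1d(blood_library, conc, MixtureSpec(protein_scale=scale))
            integrals.append(np.trapezoid(s.grid.intensity[sel][::-1], axis[sel][::-1]))
        assert np.all(np.diff(integrals) > 0)


class TestNoise:
    def test_zero_noise_identity(self, toy_library):
        mid = toy_library.ids()[0]
        g = toy_library[mid].spectrum_1d
        out = add_noise(g, 0.0, 0)
        assert np.array_equal(out.intensity, g.intensity)

    def test_flat_zero_grid_stays_zero(self):
        from metabomix import SpectrumGrid1D

        g = SpectrumGrid1D(np.linspace(9.0, 0.0, 128), np.zeros(128))
        out = add_noise(g, 0.01, 0)
        assert np.all(out.intensity == 0.0)

    def test_empirical_noise_sd(self):
        from metabomix import SpectrumGrid1D

        n = 10**6
        g = SpectrumGrid1D(np.linspace(9.0, 0.0, n), np.full(n, 5.0))
        out = add_noise(g, 0.01, 123)
        sd = np.std(out.intensity - g.intensity)
        assert sd == pytest.approx(0.05, rel=0.01)

    def test_deterministic_given_seed(self, toy_library):
        mid = toy_library.ids()[0]
        g = toy_library[mid].spectrum_1d
        a = add_noise(g, 0.01, 7)
        b = add_noise(g, 0.01, 7)
        assert np.array_equal(a.intensity, b.intensity)


class TestMixture2D:
    def test_single_metabolite_identity(self, toy_library):
        mid = toy_library.ids()[0]
        s = simulate_mixture_2d(toy_library, {mid: 1.0}, MixtureSpec(mode="jres"))
        assert np.array_equal(s.grid.intensity, toy_library[mid].spectrum_jres.intensity)

    def test_additivity(self, toy_library):
        ids = toy_library.ids()[:2]
        spec = MixtureSpec(mode="jres")
        joint = simulate_mixture_2d(toy_library, {ids[0]: 2.0, ids[1]: 3.0}, spec)
        a = simulate_mixture_2d(toy_library, {ids[0]: 2.0}, spec)
        b = simulate_mixture_2d(toy_library, {ids[1]: 3.0}, spec)
        assert np.allclose(joint.grid.intensity, a.grid.intensity + b.grid.intensity, rtol=1e-12)

    def test_cosy_mixture_symmetric(self, toy_library):
        conc = {m: float(i + 1) for i, m in enumerate(toy_library.ids())}
        s = simulate_mixture_2d(toy_library, conc, MixtureSpec(mode="cosy"))
        assert s.grid.is_symmetric(tol=1e-9)

    def test_missing_2d_grid_listed(self, separated_library):
        mid = separated_library.ids()[0]
        with pytest.raises(MixtureError, match=mid):
            simulate_mixture_2d(separated_library, {mid: 1.0}, MixtureSpec(mode="jres"))


def _discrete_design(library, n=4):
    ids = library.ids()
    return DiscreteDesign(
        metabolite_ids=ids,
        normal_stats={m: ConditionStats(100.0, 10.0) for m in ids},
        groups={"normal": GroupSpec(n=n), "case": GroupSpec(n=n, fold_changes={ids[0]: 2.0})},
    )


class TestCohort:
    def test_bit_identical_replay(self, toy_library):
        design = _discrete_design(toy_library)
        spec = MixtureSpec(
            mode="1d", shift_enabled=True, ph_sd=0.3, noise_sd=0.005, seed=11
        )
        a = simulate_cohort(toy_library, design, spec)
        b = simulate_cohort(toy_library, design, spec)
        assert a.table.concentrations.equals(b.table.concentrations)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.grid.intensity, sb.grid.intensity)
            assert sa.ph == sb.ph

    def test_label_fidelity(self, toy_library):
        design = _discrete_design(toy_library)
        res = simulate_cohort(toy_library, design, MixtureSpec(seed=3))
        for i, s in enumerate(res.spectra):
            row = res.table.concentrations.iloc[i]
            assert s.concentrations == {m: row[m] for m in res.table.metabolite_ids}

    def test_noise_does_not_perturb_concentrations(self, toy_library):
        design = _discrete_design(toy_library)
        quiet = simulate_cohort(toy_library, design, MixtureSpec(seed=5, noise_sd=0.0))
        noisy = simulate_cohort(toy_library, design, MixtureSpec(seed=5, noise_sd=0.01))
        assert quiet.table.concentrations.equals(noisy.table.concentrations)

    def test_continuous_cohort_correlation(self, separated_library):
        ids = separated_library.ids()
        a = 0.9
        design = ContinuousDesign(
            n=200,
            response_mean=25.0,
            response_sd=4.0,
            metabolites={
                m: MetaboliteResponse(200.0, 20.0, a=a if m == ids[0] else 0.0,
                                      eps_sd=np.sqrt(1 - a**2) if m == ids[0] else 1.0)
                for m in ids
            },
        )
        res = simulate_cohort(separated_library, design, MixtureSpec(seed=21))
        axis = separated_library.common_grid
        # integrate metabolite 0's exclusive window
        apex = axis[np.argmax(separated_library[ids[0]].spectrum_1d.intensity)]
        sel = np.abs(axis - apex) <= 0.2
        integrals = [
            np.trapezoid(s.grid.intensity[sel][::-1], axis[sel][::-1]) for s in res.spectra
        ]
        r = np.corrcoef(integrals, res.table.labels)[0, 1]
        assert r == pytest.approx(a, abs=0.1)

    def test_discrete_cohort_fold_change(self, separated_library):
        ids = separated_library.ids()
        design = DiscreteDesign(
            metabolite_ids=ids,
            normal_stats={m: ConditionStats(200.0, 20.0) for m in ids},
            groups={
                "normal": GroupSpec(n=100),
                "case": GroupSpec(n=100, fold_changes={ids[0]: 3.0}),
            },
        )
        res = simulate_cohort(separated_library, design, MixtureSpec(seed=9))
        axis = separated_library.common_grid
        apex = axis[np.argmax(separated_library[ids[0]].spectrum_1d.intensity)]
        sel = np.abs(axis - apex) <= 0.2
        integrals = np.array(
            [np.trapezoid(s.grid.intensity[sel][::-1], axis[sel][::-1]) for s in res.spectra]
        )
        groups = res.table.labels.to_numpy()
        ratio = integrals[groups == "case"].mean() / integrals[groups == "normal"].mean()
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_error_names_replicate(self, separated_library):
        design = _discrete_design(separated_library, n=2)
        spec = MixtureSpec(mode="jres", seed=1)  # separated_library has no 2D grids
        with pytest.raises(MixtureError, match="replicate 0"):
            simulate_cohort(separated_library, design, spec)
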