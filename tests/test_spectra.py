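"""Spectral unmixing: exact recovery, noise robustness, and the log-ratio
relation between dissociation degrees and the acidity difference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acidscale.spectra import (
    PureFormBasis,
    SpectrumMatrix,
    aggregate_pair,
    delta_pkip_from_alphas,
    unmix_spectra,
    DissociationPoint,
    SpectralUnmixer,
)


def make_basis(rng, n_wl=200):
    wl = np.linspace(250, 450, n_wl)
    spectra = {}
    for k, centers in (
        ("HA1", [280]), ("A1", [340]), ("HA2", [300, 380]), ("A2", [420]),
    ):
        eps = np.zeros_like(wl)
        for c in centers:
            eps += rng.uniform(0.5, 1.5) * np.exp(-0.5 * ((wl - c) / 20.0) ** 2)
        spectra[k] = eps
    return PureFormBasis(wl, "a1", "a2", spectra)


def mixture_from(basis, alpha1, alpha2, scale1=1.0, scale2=1.0):
    s = basis.spectra
    return (
        s["HA1"] * scale1 * (1 - alpha1) + s["A1"] * scale1 * alpha1
        + s["HA2"] * scale2 * (1 - alpha2) + s["A2"] * scale2 * alpha2
    )


class TestUnmixing:
    def test_exact_linear_recovery(self, rng):
        basis = make_basis(rng)
        y = mixture_from(basis, 0.7, 0.5)
        mix = SpectrumMatrix(basis.wavelengths, y[:, None], ["s0"])
        (pt,) = unmix_spectra(mix, basis)
        assert pt.usable
        assert pt.alpha1 == pytest.approx(0.7, abs=1e-10)
        assert pt.alpha2 == pytest.approx(0.5, abs=1e-10)

    def test_pure_single_acid_flagged_unusable(self, rng):
        basis = make_basis(rng)
        y = basis.spectra["HA1"].copy()
        mix = SpectrumMatrix(basis.wavelengths, y[:, None], ["s0"])
        (pt,) = unmix_spectra(mix, basis)
        assert not pt.usable
        assert "acid 2 absent" in pt.reason
        assert pt.alpha1 == pytest.approx(0.0, abs=1e-8)
        assert pt.alpha2 is None

    def test_noisy_recovery_within_tolerance(self, rng):
        basis = make_basis(rng)
        y = mixture_from(basis, 0.6, 0.4) + rng.normal(0, 0.002, basis.wavelengths.size)
        mix = SpectrumMatrix(basis.wavelengths, y[:, None], ["s0"])
        (pt,) = unmix_spectra(mix, basis)
        assert pt.usable
        assert pt.alpha1 == pytest.approx(0.6, abs=0.02)
        assert pt.alpha2 == pytest.approx(0.4, abs=0.02)

    def test_scale_invariance(self, rng):
        """A common positive factor on all spectra leaves alpha unchanged."""
        basis = make_basis(rng)
        y = mixture_from(basis, 0.3, 0.8)
        scaled = PureFormBasis(
            basis.wavelengths, "a1", "a2",
            {k: 7.5 * v for k, v in basis.spectra.items()},
        )
        mix = SpectrumMatrix(basis.wavelengths, 7.5 * y[:, None], ["s0"])
        (pt,) = unmix_spectra(mix, scaled)
        assert pt.alpha1 == pytest.approx(0.3, abs=1e-9)
        assert pt.alpha2 == pytest.approx(0.8, abs=1e-9)

    def test_ill_conditioned_basis_rejected(self, rng):
        basis = make_basis(rng)
        spectra = dict(basis.spectra)
        spectra["A2"] = spectra["HA2"] * 1.0000001  # nearly collinear pair
        bad = PureFormBasis(basis.wavelengths, "a1", "a2", spectra)
        with pytest.raises(ValueError, match="ill-conditioned"):
            SpectralUnmixer().fit(bad)

    def test_wavelength_grid_mismatch_rejected(self, rng):
        basis = make_basis(rng)
        other = SpectrumMatrix(
            basis.wavelengths + 1.0,
            mixture_from(basis, 0.5, 0.5)[:, None],
            ["s0"],
        )
        with pytest.raises(ValueError, match="common wavelength grid"):
            unmix_spectra(other, basis)


class TestDeltaPkip:
    @pytest.mark.parametrize(
        "a1, a2, expected",
        [
            (0.5, 0.5, 0.0),
            (0.9, 0.5, math.log10(9)),
            (0.5, 0.9, -math.log10(9)),
        ],
    )
    def test_direct_values(self, a1, a2, expected):
        assert delta_pkip_from_alphas(a1, a2) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("a1, a2", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_endpoints_rejected(self, a1, a2):
        with pytest.raises(ValueError, match="strictly inside"):
            delta_pkip_from_alphas(a1, a2)

    @given(
        a1=st.floats(0.01, 0.99), a2=st.floats(0.01, 0.99),
    )
    @settings(deadline=None)
    def test_antisymmetry(self, a1, a2):
        assert delta_pkip_from_alphas(a1, a2) == pytest.approx(
            -delta_pkip_from_alphas(a2, a1), abs=1e-10
        )

    @given(
        a1=st.floats(0.02, 0.97), a2=st.floats(0.02, 0.97),
        eps=st.floats(0.005, 0.02),
    )
    @settings(deadline=None)
    def test_monotone_in_alphas(self, a1, a2, eps):
        base = delta_pkip_from_alphas(a1, a2)
        assert delta_pkip_from_alphas(a1 + eps, a2) > base
        assert delta_pkip_from_alphas(a1, a2 + eps) < base


class TestAggregation:
    def test_mean_and_spread(self):
        # alphas chosen so the per-point estimates are 0.50, 0.52, 0.48
        pts = []
        for i, target in enumerate([0.50, 0.52, 0.48]):
            a2 = 0.5
            a1 = 10**target * a2 / (1 - a2 + 10**target * a2)
            pts.append(DissociationPoint(f"s{i}", a1, a2, True))
        res = aggregate_pair(pts, "x", "y")
        assert res.delta_pkip == pytest.approx(0.50, abs=1e-12)
        assert res.spread == pytest.approx(0.02, abs=1e-10)
        assert res.n_points == 3

    def test_single_point(self):
        a2 = 0.4
        a1 = 10**0.30 * a2 / (1 - a2 + 10**0.30 * a2)
        res = aggregate_pair([DissociationPoint("s0", a1, a2, True)], "x", "y")
        assert res.delta_pkip == pytest.approx(0.30, abs=1e-12)
        assert res.spread == 0.0

    def test_no_usable_points_lists_reasons(self):
        pts = [DissociationPoint("s0", None, None, False, "acid 2 absent")]
        with pytest.raises(ValueError, match="acid 2 absent"):
            aggregate_pair(pts, "x", "y")

    def test_aggregate_antisymmetric_under_role_swap(self, rng):
        basis = make_basis(rng)
        cols = np.column_stack(
            [mixture_from(basis, a1, a2) for a1, a2 in [(0.7, 0.4), (0.5, 0.2), (0.8, 0.6)]]
        )
        mix = SpectrumMatrix(basis.wavelengths, cols, ["s0", "s1", "s2"])
        fwd = aggregate_pair(unmix_spectra(mix, basis), "a1", "a2")
        swapped = PureFormBasis(
            basis.wavelengths, "a2", "a1",
            {"HA1": basis.spectra["HA2"], "A1": basis.spectra["A2"],
             "HA2": basis.spectra["HA1"], "A2": basis.spectra["A1"]},
        )
        rev = aggregate_pair(unmix_spectra(mix, swapped), "a2", "a1")
        assert fwd.delta_pkip == pytest.approx(-rev.delta_pkip, abs=1e-9)
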