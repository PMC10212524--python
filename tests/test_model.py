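"""Forward-model unit and property tests."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prenotrace as pt
from prenotrace.masses import ELECTRON_MASS, MONOISOTOPIC_MASS

from conftest import brute_force_envelope


class TestBinomialEnvelope:
    @pytest.mark.parametrize(
        "n, p, expected",
        [
            (2, 0.5, [0.25, 0.5, 0.25]),
            (0, 0.3, [1.0]),
        ],
    )
    def test_closed_form(self, n, p, expected):
        env = pt.binomial_envelope(n, p)
        np.testing.assert_allclose(env.intensities, expected, atol=1e-14)

    def test_zero_probability_is_delta(self):
        env = pt.binomial_envelope(80, 0.0)
        assert env[0] == 1.0
        assert env.intensities[1:].sum() == 0.0

    def test_matches_direct_binomial_evaluation(self):
        """Natural 13C abundance of an 80-carbon dolichol backbone."""
        env = pt.binomial_envelope(80, 0.0102)
        direct = np.array(
            [comb(80, k) * 0.0102**k * 0.9898 ** (80 - k) for k in range(81)]
        )
        np.testing.assert_allclose(env.intensities, direct, atol=1e-14)
        assert env[0] == pytest.approx(0.9898**80, rel=1e-12)

    def test_rejects_invalid_probability(self):
        with pytest.raises(pt.DomainError):
            pt.binomial_envelope(10, 1.5)


class TestDeuteriumCountDistribution:
    def test_no_labeled_units_is_delta(self, mvl):
        dist = pt.deuterium_count_distribution(0, mvl)
        np.testing.assert_allclose(dist, [1.0])

    def test_perfect_substrate_unit_mode(self):
        prec = pt.PrecursorSpec("MVL", d=3, q=0.0)
        dist = pt.deuterium_count_distribution(2, prec, "unit")
        assert dist[6] == pytest.approx(1.0)

    def test_unit_mode_enumeration(self):
        """Two labeled MVL units, q = 0.007: counts only at multiples of 3."""
        q = 0.007
        prec = pt.PrecursorSpec("MVL", d=3, q=q)
        dist = pt.deuterium_count_distribution(2, prec, "unit")
        assert dist[6] == pytest.approx((1 - q) ** 2, rel=1e-12)
        assert dist[3] == pytest.approx(2 * (1 - q) * q, rel=1e-12)
        assert dist[0] == pytest.approx(q**2, rel=1e-12)
        assert dist[[1, 2, 4, 5]].sum() == 0.0

    def test_site_mode_spreads_between_multiples(self):
        prec = pt.PrecursorSpec("MVL", d=3, q=0.1)
        dist = pt.deuterium_count_distribution(2, prec, "site")
        # Binomial(6, 0.9): satellite masses at 5, 4, ... are nonzero
        assert dist[5] > 0
        assert dist[5] == pytest.approx(comb(6, 5) * 0.9**5 * 0.1, rel=1e-12)


class TestForwardEnvelope:
    def test_unlabeled_reduces_to_c13_envelope(self, dol16, mvl):
        z = pt.PathwayDistribution.delta(0, 16)
        env = pt.forward_envelope(dol16, mvl, z, pt.ModelConfig(p13C=0.0102))
        ref = pt.binomial_envelope(80, 0.0102)
        n = len(env)
        np.testing.assert_allclose(env.intensities, ref.intensities[:n], atol=1e-12)

    def test_pure_label_single_peak(self, dol16, mvl):
        """With q = 0 and no 13C, a fully labeled molecule is one peak at d*i."""
        prec = pt.PrecursorSpec("MVL", d=3, q=0.0)
        for i in (0, 5, 16):
            z = pt.PathwayDistribution.delta(i, 16)
            env = pt.forward_envelope(dol16, prec, z, pt.ModelConfig(p13C=0.0))
            assert env[3 * i] == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["unit", "site"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_exhaustive_enumeration(self, tiny_compound, mode, seed):
        rng = np.random.default_rng(seed)
        z = rng.dirichlet(np.ones(5))
        q, p13C = 0.03, 0.0102
        prec = pt.PrecursorSpec("DX", d=2, q=q)
        env = pt.forward_envelope(
            tiny_compound, prec, pt.PathwayDistribution(z),
            pt.ModelConfig(p13C=p13C, purity_mode=mode),
        )
        oracle = brute_force_envelope(4, 20, 2, q, p13C, z, mode)
        n = len(env)
        assert np.abs(env.intensities - oracle[:n]).max() <= 1e-12

    def test_dimension_mismatch_rejected(self, dol16, mvl):
        z = pt.PathwayDistribution.delta(0, 11)
        with pytest.raises(pt.ContractViolation):
            pt.forward_envelope(dol16, mvl, z)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_normalized_and_moment_identity(self, seed):
        """Envelope sums to one; mean shift equals n*p13C + d*(1-q)*E[z]."""
        rng = np.random.default_rng(seed)
        comp = pt.get_compound("Pren-11")
        prec = pt.PrecursorSpec("DX", d=2, q=rng.uniform(0, 0.2))
        z = pt.PathwayDistribution(rng.dirichlet(np.ones(12)))
        env = pt.forward_envelope(comp, prec, z)
        assert abs(env.intensities.sum() - 1.0) <= 1e-12
        assert np.all(env.intensities >= 0)
        assert env.mean_shift() == pytest.approx(
            pt.analytic_mean_shift(comp, prec, z), abs=1e-10
        )

    def test_linear_in_z(self, pren11, dx):
        rng = np.random.default_rng(7)
        w = rng.dirichlet(np.ones(12))
        config = pt.ModelConfig(p13C=0.0102)
        mixed = pt.forward_envelope(pren11, dx, pt.PathwayDistribution(w), config)
        parts = np.zeros(len(mixed))
        for i, wi in enumerate(w):
            delta = pt.forward_envelope(
                pren11, dx, pt.PathwayDistribution.delta(i, 11), config
            )
            parts[: len(delta)] += wi * delta.intensities
        np.testing.assert_allclose(mixed.intensities, parts, atol=1e-12)

    def test_no_purity_no_c13_reindexes_z(self, pren11):
        rng = np.random.default_rng(3)
        z = rng.dirichlet(np.ones(12))
        prec = pt.PrecursorSpec("DX", d=2, q=0.0)
        env = pt.forward_envelope(
            pren11, prec, pt.PathwayDistribution(z), pt.ModelConfig(p13C=0.0)
        )
        for i, zi in enumerate(z):
            assert env[2 * i] == pytest.approx(zi, abs=1e-12)


class TestMassBookkeeping:
    @pytest.mark.parametrize(
        "compound, precursor, expected",
        [("Dol-16", "MVL", 48), ("Pren-11", "DX", 22), ("Pren-11", "MVL", 33)],
    )
    def test_expected_max_shift(self, compound, precursor, expected):
        assert pt.expected_max_shift(
            pt.get_compound(compound), pt.get_precursor(precursor)
        ) == expected

    def test_molecular_ion_is_neutral_minus_electron(self, dol16):
        neutral = 80 * MONOISOTOPIC_MASS["C"] + 132 * MONOISOTOPIC_MASS["H"] \
            + MONOISOTOPIC_MASS["O"]
        assert pt.adduct_base_mz(dol16, "M+") == pytest.approx(
            neutral - ELECTRON_MASS, abs=1e-9
        )

    def test_protonated_geraniol_against_atomic_mass_sum(self):
        comp = pt.CompoundSpec(
            name="geraniol", family="generic", n_units=2,
            formula={"C": 10, "H": 18, "O": 1},
        )
        # independent sum of IUPAC monoisotopic masses
        expected = 10 * 12.0 + 19 * 1.00782503207 + 15.9949146196 - 0.000548579909
        assert pt.adduct_base_mz(comp, "[M+H]+") == pytest.approx(expected, abs=1e-6)

    def test_sodiated_dol16_against_atomic_mass_sum(self, dol16):
        expected = (
            80 * 12.0 + 132 * 1.00782503207 + 15.9949146196
            + 22.9897692809 - 0.000548579909
        )
        assert pt.adduct_base_mz(dol16, "[M+Na]+") == pytest.approx(expected, abs=1e-6)

    def test_unknown_adduct_rejected(self, dol16):
        with pytest.raises(pt.ConfigurationError):
            pt.adduct_base_mz(dol16, "[M+Cs]+")


class TestSpecs:
    def test_polyprenol_carbon_rule_enforced(self):
        with pytest.raises(pt.ContractViolation):
            pt.CompoundSpec(
                name="bad", family="polyprenol", n_units=11,
                formula={"C": 54, "H": 90, "O": 1},
            )

    def test_precursor_validation(self):
        with pytest.raises(pt.DomainError):
            pt.PrecursorSpec("DX", d=0, q=0.01)
        with pytest.raises(pt.DomainError):
            pt.PrecursorSpec("DX", d=2, q=1.5)

    def test_registry_presets(self):
        assert pt.get_compound("Pren-11").n_carbons == 55
        assert pt.get_compound("Dol-16").n_carbons == 80
        assert pt.get_compound("campesterol").n_carbons == 28
        assert pt.get_compound("sitosterol").n_carbons == 29
        assert pt.get_precursor("DX").d == 2
        assert pt.get_precursor("MVL").d == 3
        with pytest.raises(pt.ConfigurationError):
            pt.get_compound("Dol-99")
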