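"""Natural-abundance isotope math, deconvolution, MIDA and deisotoping."""

import numpy as np
import pytest
import sympy
from scipy.stats import binom

from lipidomix import (
    ElementalFormula,
    IsotopologueProfile,
    TracerSimConfig,
    correct_isotopic_overlap,
    estimate_fractional_synthesis,
    estimate_precursor_enrichment,
    excess_distribution,
    fame_formula,
    fame_nominal_mass,
    generate_isotopologue_series,
    mida_estimate,
    na_correction,
    natural_abundance_distribution,
    parse_lipid_name,
)
from lipidomix.isotopes import ISOTOPE_SHIFT_ABUNDANCES, _na_vector


def na_oracle(formula: ElementalFormula, k_max: int) -> np.ndarray:
    """Exhaustive symbolic polynomial-expansion oracle.

    The mass-shift distribution is the product over elements of
    (sum_i a_i x^i)^n expanded with exact rational arithmetic; this never
    touches the convolution code under test.
    """
    x = sympy.Symbol("x")
    poly = sympy.Integer(1)
    for el, n in formula.counts.items():
        per_atom = sum(
            sympy.Rational(str(a)) * x**i
            for i, a in enumerate(ISOTOPE_SHIFT_ABUNDANCES[el])
        )
        poly *= per_atom**n
    coeffs = sympy.Poly(sympy.expand(poly), x).all_coeffs()[::-1]
    out = np.zeros(k_max + 1)
    for i, c in enumerate(coeffs[: k_max + 1]):
        out[i] = float(c)
    return out / out.sum()


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C", (0.9893, 0.0107)),
        ("O", (0.99757, 0.00038, 0.00205)),
    ],
)
def test_single_atom_equals_elemental_abundance(text, expected):
    profile = natural_abundance_distribution(
        ElementalFormula.parse(text), len(expected) - 1)
    np.testing.assert_allclose(profile.abundances, expected, atol=1e-12)


def test_methyl_palmitate_distribution():
    """FAME of palmitate: M0 ~ 0.826 and an M1/M0 ratio of ~0.19."""
    profile = natural_abundance_distribution(
        ElementalFormula.parse("C17H34O2"), 8)
    assert profile.abundances[0] == pytest.approx(0.826, abs=5e-3)
    ratio = profile.abundances[1] / profile.abundances[0]
    assert ratio == pytest.approx(0.19, abs=5e-3)
    oracle = na_oracle(ElementalFormula.parse("C17H34O2"), 8)
    np.testing.assert_allclose(profile.abundances, oracle, atol=1e-6)


@pytest.mark.parametrize(
    "text",
    ["C10H12", "C5H10O2", "C2H5NO2S", "C6H8O6", "C3H7O6P", "CHNOPS",
     "C12H13", "H2O", "C20H5", "N5O5S5"],
)
def test_na_distribution_matches_polynomial_oracle(text):
    """Agreement with the exact expansion for formulas up to 25 atoms."""
    formula = ElementalFormula.parse(text)
    assert formula.n_atoms <= 25
    k = 6
    got = natural_abundance_distribution(formula, k).abundances
    np.testing.assert_allclose(got, na_oracle(formula, k), atol=1e-9)


def test_na_distribution_rejects_bad_kmax():
    with pytest.raises(ValueError):
        natural_abundance_distribution(ElementalFormula.parse("C"), 0)


# ---------------------------------------------------------------------------
# NA correction


def test_na_correction_of_pure_na_is_delta():
    formula = ElementalFormula.parse("C17H34O2")
    measured = natural_abundance_distribution(formula, 8)
    x = na_correction(measured)
    expected = np.zeros(9)
    expected[0] = 1.0
    np.testing.assert_allclose(x.abundances, expected, atol=1e-12)


def test_na_correction_inverts_forward_convolution():
    """0.7*delta0 + 0.3*Binomial(8, 0.1) recovered to 1e-10."""
    formula = ElementalFormula.parse("C17H34O2")
    k = 9
    na = _na_vector(formula)[:k]
    mix = 0.7 * np.eye(1, k, 0)[0] + 0.3 * binom.pmf(np.arange(k), 8, 0.1)
    measured = np.zeros(k)
    for j in range(k):
        measured[j] = np.dot(mix[: j + 1][::-1], na[: j + 1])
    profile = IsotopologueProfile("mix", formula, measured / measured.sum())
    corrected = na_correction(profile)
    np.testing.assert_allclose(corrected.abundances, mix / mix.sum(),
                               atol=1e-10)


def test_na_correction_rejects_large_negatives():
    formula = ElementalFormula.parse("C17H34O2")
    measured = natural_abundance_distribution(formula, 8).abundances.copy()
    measured[1] *= 0.5  # large deficit -> strongly negative component
    profile = IsotopologueProfile("noisy", formula,
                                  measured / measured.sum())
    with pytest.raises(ValueError, match="negative corrected"):
        na_correction(profile)


# ---------------------------------------------------------------------------
# Excess distributions and MIDA estimators


def test_excess_is_zero_for_identical_profiles_and_sums_to_zero():
    formula = ElementalFormula.parse("C17H34O2")
    na = natural_abundance_distribution(formula, 8)
    np.testing.assert_allclose(excess_distribution(na, na), 0.0, atol=1e-15)
    cfg = TracerSimConfig(noise_cv=0.0)
    (lab, ctl), = generate_isotopologue_series(cfg)
    em = excess_distribution(na_correction(lab), na_correction(ctl))
    assert em.sum() == pytest.approx(0.0, abs=1e-9)


def test_excess_m2_matches_binomial_formula():
    """EM2 = f * B(2; 8, 0.1) = 0.3 * 28 * 0.01 * 0.9^6 = 0.044641."""
    cfg = TracerSimConfig(precursor_enrichment=0.1, fractional_synthesis=0.3,
                          noise_cv=0.0)
    (lab, ctl), = generate_isotopologue_series(cfg)
    em = excess_distribution(na_correction(lab), na_correction(ctl))
    assert em[2] == pytest.approx(0.3 * 28 * 0.01 * 0.9**6, abs=1e-9)


def test_excess_length_mismatch_is_an_error():
    f = ElementalFormula.parse("C2H4O2")
    a = natural_abundance_distribution(f, 4)
    b = natural_abundance_distribution(f, 5)
    with pytest.raises(ValueError, match="length mismatch"):
        excess_distribution(a, b)


@pytest.mark.parametrize(
    "r, expected_p",
    [(0.22222222222222221, 0.1), (0.0, 0.0), (2.0, 0.5)],
)
def test_precursor_enrichment_closed_form(r, expected_p):
    em = np.zeros(9)
    em[2] = 0.05
    em[3] = r * em[2]
    p = estimate_precursor_enrichment(em, 8)
    assert p == pytest.approx(expected_p, abs=1e-12)


def test_precursor_enrichment_bisection_agrees_with_closed_form():
    em = np.zeros(9)
    em[2], em[3] = 0.0446, 0.0119
    closed = estimate_precursor_enrichment(em, 8, method="closed_form")
    bisect = estimate_precursor_enrichment(em, 8, method="bisect")
    assert bisect == pytest.approx(closed, abs=1e-10)


def test_precursor_enrichment_error_paths():
    em = np.zeros(9)
    with pytest.raises(ValueError, match="no measurable M2"):
        estimate_precursor_enrichment(em, 8)
    em[2], em[3] = 0.05, -0.01
    with pytest.raises(ValueError, match="negative excess ratio"):
        estimate_precursor_enrichment(em, 8)


def test_fractional_synthesis_from_m2_excess():
    em = np.zeros(9)
    em[2] = 0.044641
    assert estimate_fractional_synthesis(em, 0.1, 8) == pytest.approx(
        0.300, abs=1e-3)
    em[2] = 0.0
    assert estimate_fractional_synthesis(em, 0.1, 8) == 0.0
    em[2] = 0.01
    with pytest.raises(ValueError, match="inconsistent"):
        estimate_fractional_synthesis(em, 0.0, 8)


def test_mida_round_trip_noise_free_grid():
    """p and f recovered to 1e-8 over the full (p, f) grid at zero noise."""
    for p in (0.02, 0.05, 0.1, 0.2):
        for f in (0.05, 0.3, 0.8):
            cfg = TracerSimConfig(precursor_enrichment=p,
                                  fractional_synthesis=f, noise_cv=0.0)
            (lab, ctl), = generate_isotopologue_series(cfg)
            res = mida_estimate(lab, ctl)
            assert res.precursor_enrichment == pytest.approx(p, abs=1e-8)
            assert res.fractional_synthesis == pytest.approx(f, abs=1e-8)


def test_mida_dose_series_orders_fractional_synthesis():
    """Recovered f is strictly increasing along an in-vivo-like dose series."""
    cfg = TracerSimConfig(noise_cv=0.02, seed=11)
    doses = [(0.05, 0.04), (0.1, 0.15), (0.15, 0.30)]
    estimates = []
    for lab, ctl in generate_isotopologue_series(cfg, doses):
        estimates.append(mida_estimate(lab, ctl).fractional_synthesis)
    assert estimates[0] < estimates[1] < estimates[2]


# ---------------------------------------------------------------------------
# FAME masses


@pytest.mark.parametrize(
    "label, formula, mass",
    [
        ("FA 16:0", "C17H34O2", 270),
        ("FA 18:1", "C19H36O2", 296),
        ("FA 2:0", "C3H6O2", 74),
    ],
)
def test_fame_formula_and_nominal_mass(label, formula, mass):
    fa = parse_lipid_name(label)
    assert fame_formula(fa).hill() == formula
    assert fame_nominal_mass(fa) == mass


def test_fame_mass_rejects_non_fa():
    with pytest.raises(ValueError, match="not an FA"):
        fame_nominal_mass(parse_lipid_name("PC 34:1"))


# ---------------------------------------------------------------------------
# Species-level isotopic overlap


def _pc_formula(c: int, d: int) -> ElementalFormula:
    # diacyl-PC: glycerophosphocholine backbone plus two acyl chains
    return ElementalFormula({"C": c + 8, "H": 2 * c + 16 - 2 * d,
                             "N": 1, "O": 8, "P": 1})


def test_overlap_correction_simple_subtraction():
    """A 5% a2 of a 100-intensity donor removes 5 units from the +2 Da peak."""
    sp_a, sp_b = parse_lipid_name("PC 34:2"), parse_lipid_name("PC 34:1")
    report = correct_isotopic_overlap(
        [(sp_a, 100.0, _pc_formula(34, 2)), (sp_b, 105.0, _pc_formula(34, 1))],
        a2_factors={"PC 34:2": 0.05},
    )
    corrected = report.corrected_intensities()
    assert corrected["PC 34:2"] == 100.0
    assert corrected["PC 34:1"] == pytest.approx(100.0)


def test_overlap_correction_single_species_unchanged():
    sp = parse_lipid_name("PC 34:1")
    report = correct_isotopic_overlap([(sp, 42.0, _pc_formula(34, 1))])
    assert report.corrected_intensities() == {"PC 34:1": 42.0}


def test_overlap_correction_rejects_duplicates():
    sp = parse_lipid_name("PC 34:1")
    with pytest.raises(ValueError, match="duplicate"):
        correct_isotopic_overlap([(sp, 1.0, _pc_formula(34, 1)),
                                  (sp, 2.0, _pc_formula(34, 1))])


def test_overlap_correction_inverts_forward_cascade():
    """Exact inverse of the a2 cascade on a 36:3/36:2/36:1 chain."""
    chain = [(36, d) for d in (3, 2, 1)]
    species = [parse_lipid_name(f"PC {c}:{d}") for c, d in chain]
    formulas = [_pc_formula(c, d) for c, d in chain]
    true = {sp.label: v for sp, v in zip(species, (80.0, 60.0, 40.0))}
    # forward simulation: each species' measured intensity gains its
    # donor's M+2 contribution (donor = one more double bond, true value)
    a2 = {}
    for sp, f in zip(species, formulas):
        na = _na_vector(f)
        a2[sp.label] = na[2] / na[0]
    measured = dict(true)
    for donor, acceptor in (("PC 36:3", "PC 36:2"), ("PC 36:2", "PC 36:1")):
        measured[acceptor] += a2[donor] * true[donor]
    report = correct_isotopic_overlap(
        [(sp, measured[sp.label], f) for sp, f in zip(species, formulas)])
    corrected = report.corrected_intensities()
    for label, v in true.items():
        assert corrected[label] == pytest.approx(v, abs=1e-10)
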