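"""Isotope mathematics and MIDA (mass isotopomer distribution analysis).

Covers four steps of a ¹³C-acetate tracer workflow on GC-MS fatty-acid
methyl esters (FAMEs) and ESI-MS/MS glycerophospholipids:

1. natural-abundance (NA) isotopologue distributions of a molecular formula,
2. NA deconvolution of a measured isotopologue profile,
3. excess mass isotopomer distributions (labeled minus unlabeled control),
4. MIDA estimation of the precursor-pool enrichment ``p`` and the fractional
   synthesis ``f`` of a polymer built from ``n`` identical subunits
   (palmitate: n = 8 acetyl units).

The polymerization model: a newly synthesized molecule draws its ``n``
subunits i.i.d. from a precursor pool with ¹³C enrichment ``p``, so the
label-count distribution of new molecules is Binomial(n, p).  The measured
pool is a (1 − f)/f mixture of pre-existing (unlabeled) and new molecules.
On NA-deconvolved profiles the excess distribution is ``EM = f·(B(·; n, p)
− δ₀)``, hence ``EM₃/EM₂ = B(3)/B(2)`` determines ``p`` in closed form and
``f = EM₂ / B(2; n, p)``.

Isotopologues are indexed by nominal mass shift (M0, M1, ...); quadrupole
instruments do not resolve isobaric fine structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import brentq
from scipy.stats import binom

from .datamodel import ElementalFormula, LipidSpeciesName

__all__ = [
    "ISOTOPE_SHIFT_ABUNDANCES",
    "IsotopologueProfile",
    "MIDAResult",
    "OverlapCorrectionReport",
    "natural_abundance_distribution",
    "na_correction",
    "excess_distribution",
    "estimate_precursor_enrichment",
    "estimate_fractional_synthesis",
    "mida_estimate",
    "fame_formula",
    "fame_nominal_mass",
    "correct_isotopic_overlap",
]


#: Per-atom isotope abundances indexed by nominal mass shift, IUPAC 2013
#: representative values (13C 0.0107, 2H 0.000115, 17O 0.00038, 18O 0.00205).
#: Overridable via the ``abundances`` argument of
#: :func:`natural_abundance_distribution`.
ISOTOPE_SHIFT_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}


@dataclass
class IsotopologueProfile:
    """Fractional abundances M0..Mk of one analyte."""

    analyte: str
    formula: ElementalFormula
    abundances: np.ndarray
    normalized: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1 or len(self.abundances) == 0:
            raise ValueError("abundances must be a non-empty vector")
        if self.normalized:
            total = self.abundances.sum()
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"normalized profile sums to {total}, not 1")

    def __len__(self) -> int:
        return len(self.abundances)

    def normalize(self) -> "IsotopologueProfile":
        total = self.abundances.sum()
        if total <= 0:
            raise ValueError("cannot normalize a profile with non-positive sum")
        return IsotopologueProfile(self.analyte, self.formula,
                                   self.abundances / total, normalized=True,
                                   diagnostics=dict(self.diagnostics))


def _vector_power(base: np.ndarray, n: int) -> np.ndarray:
    """Distribution of the sum of ``n`` i.i.d. mass shifts (repeated convolution)."""
    result = np.array([1.0])
    acc = base
    while n > 0:
        if n & 1:
            result = np.convolve(result, acc)
        n >>= 1
        if n:
            acc = np.convolve(acc, acc)
    return result


def _na_vector(formula: ElementalFormula,
               abundances: dict[str, tuple[float, ...]] | None = None
               ) -> np.ndarray:
    """Full (untruncated, unit-sum) NA mass-shift distribution of a formula."""
    table = dict(ISOTOPE_SHIFT_ABUNDANCES)
    if abundances:
        table.update(abundances)
    out = np.array([1.0])
    for el, n in formula.counts.items():
        per_atom = np.asarray(table[el], dtype=float)
        out = np.convolve(out, _vector_power(per_atom, n))
    return out


def natural_abundance_distribution(
    formula: ElementalFormula,
    k_max: int,
    *,
    abundances: dict[str, tuple[float, ...]] | None = None,
    analyte: str = "",
) -> IsotopologueProfile:
    """Natural-abundance isotopologue distribution of ``formula`` up to Mk.

    Convolves per-element mass-shift distributions (each element's per-atom
    distribution raised to its atom count by repeated convolution), truncates
    at ``k_max`` and renormalizes the retained mass.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    full = _na_vector(formula, abundances)
    trunc = np.zeros(k_max + 1)
    upto = min(len(full), k_max + 1)
    trunc[:upto] = full[:upto]
    return IsotopologueProfile(analyte or formula.hill(), formula,
                               trunc / trunc.sum(), normalized=True)


def na_correction(measured: IsotopologueProfile,
                  formula: ElementalFormula | None = None,
                  *,
                  clamp_threshold: float = 1e-3,
                  keep_negative: bool = False) -> IsotopologueProfile:
    """Deconvolve natural abundance from a measured isotopologue profile.

    Solves the lower-triangular system ``C x = measured`` where column ``j``
    of ``C`` is the NA distribution of ``formula`` shifted to start at Mj.
    Small negative components (greater than ``-clamp_threshold`` after unit
    normalization) are clamped to zero and counted in the diagnostics; larger
    negatives raise.  With ``keep_negative=True`` negative components are
    retained instead (noise-induced negatives are mean-zero, so keeping them
    leaves downstream excess distributions unbiased).
    """
    formula = formula or measured.formula
    y = np.asarray(measured.abundances, dtype=float)
    k = len(y)
    na = _na_vector(formula)
    col = np.zeros(k)
    col[: min(k, len(na))] = na[: min(k, len(na))]
    C = np.zeros((k, k))
    for j in range(k):
        C[j:, j] = col[: k - j]
    if np.min(np.abs(np.diag(C))) < 1e-12:  # cannot occur for valid NA columns
        raise ValueError("ill-conditioned natural-abundance matrix")
    x = solve_triangular(C, y, lower=True)
    total = x.sum()
    if total <= 0:
        raise ValueError("corrected profile has non-positive total")
    x = x / total
    negatives = np.where(x < 0)[0]
    if keep_negative:
        return IsotopologueProfile(
            measured.analyte, formula, x, normalized=False,
            diagnostics={"negative_components": int(len(negatives))},
        )
    bad = negatives[x[negatives] < -clamp_threshold]
    if len(bad):
        raise ValueError(
            f"negative corrected abundances beyond tolerance at indices "
            f"{bad.tolist()}: {x[bad].tolist()}"
        )
    clamped = len(negatives)
    x = np.clip(x, 0.0, None)
    x = x / x.sum()
    return IsotopologueProfile(
        measured.analyte, formula, x, normalized=True,
        diagnostics={"clamped_negative": int(clamped)},
    )


def excess_distribution(labeled: IsotopologueProfile,
                        control: IsotopologueProfile) -> np.ndarray:
    """Excess mass isotopomer distribution EM = labeled − control.

    Both profiles must be normalized (and, for exact binomial arithmetic,
    NA-corrected) and of equal length; EM sums to zero by construction.
    """
    if len(labeled) != len(control):
        raise ValueError(
            f"profile length mismatch: {len(labeled)} vs {len(control)}"
        )
    return np.asarray(labeled.abundances) - np.asarray(control.abundances)


def estimate_precursor_enrichment(
    EM: np.ndarray,
    n_subunits: int,
    ratio_pair: tuple[int, int] = (3, 2),
    *,
    method: str = "closed_form",
) -> float:
    """Precursor-pool enrichment ``p`` from the excess ratio EM_{k+1}/EM_k.

    For the default pair (3, 2): ``r = EM3/EM2`` and
    ``B(k+1; n, p)/B(k; n, p) = r`` gives
    ``p = r(k+1) / (n − k + r(k+1))``, i.e. ``p = r/(2 + r)`` for n = 8,
    k = 2.  ``method="bisect"`` solves the same binomial ratio numerically
    for general pairs and agrees with the closed form.
    """
    EM = np.asarray(EM, dtype=float)
    hi, k = ratio_pair
    if hi != k + 1:
        raise ValueError("ratio pair must be consecutive isotopologues (k+1, k)")
    if k >= n_subunits:
        raise ValueError("ratio index must be below the subunit count")
    if EM[k] <= 0:
        raise ValueError("no measurable M%d excess" % k)
    r = EM[hi] / EM[k]
    if r < 0:
        raise ValueError("negative excess ratio")
    if method == "closed_form":
        return r * (k + 1) / ((n_subunits - k) + r * (k + 1))
    if method == "bisect":
        if r == 0:
            return 0.0

        def g(p: float) -> float:
            return binom.pmf(hi, n_subunits, p) / binom.pmf(k, n_subunits, p) - r

        return brentq(g, 1e-12, 1 - 1e-12, xtol=1e-14)
    raise ValueError(f"unknown method {method!r}")


def estimate_fractional_synthesis(EM: np.ndarray, p: float,
                                  n_subunits: int) -> float:
    """Fractional synthesis ``f = EM2 / B(2; n, p)``.

    EM2 is the measured M2 excess; B(2; n, p) is the asymptotic M2 abundance
    at 100% new synthesis.  The result is clamped to [0, 1]; use
    :func:`mida_estimate` to retain pre-clamp values and diagnostics.
    """
    EM = np.asarray(EM, dtype=float)
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p == 0:
        if abs(EM[2]) > 1e-12:
            raise ValueError("p = 0 is inconsistent with nonzero M2 excess")
        return 0.0
    denom = binom.pmf(2, n_subunits, p)
    return float(np.clip(EM[2] / denom, 0.0, 1.0))


@dataclass
class MIDAResult:
    """Precursor enrichment and fractional synthesis with diagnostics."""

    analyte: str
    n_subunits: int
    precursor_enrichment: float
    fractional_synthesis: float
    excess_distribution: np.ndarray
    em_ratio: float
    diagnostics: dict = field(default_factory=dict)


def mida_estimate(
    labeled: IsotopologueProfile,
    control: IsotopologueProfile,
    *,
    n_subunits: int = 8,
    ratio_pair: tuple[int, int] = (3, 2),
    na_correct: bool = True,
) -> MIDAResult:
    """Full MIDA pipeline: (NA-correct), excess, enrichment, synthesis.

    With ``na_correct=True`` (default) both profiles are NA-deconvolved
    before the excess distribution is formed; the binomial ratio formulas
    are exact only on deconvolved distributions.  Deconvolution keeps
    noise-induced negative components (they are mean-zero, so the excess
    distribution stays unbiased); their count is reported in the
    diagnostics.
    """
    if na_correct:
        labeled = na_correction(labeled, keep_negative=True)
        control = na_correction(control, keep_negative=True)
    EM = excess_distribution(labeled, control)
    diagnostics = {"negative_excess_count": int((EM < 0).sum())}
    p = estimate_precursor_enrichment(EM, n_subunits, ratio_pair)
    hi, k = ratio_pair
    r = EM[hi] / EM[k]
    denom = binom.pmf(2, n_subunits, p) if p > 0 else np.nan
    f_raw = EM[2] / denom if p > 0 else 0.0
    f = float(np.clip(f_raw, 0.0, 1.0))
    p_clamped = float(np.clip(p, 0.0, 1.0))
    diagnostics.update({
        "f_pre_clamp": float(f_raw),
        "p_pre_clamp": float(p),
        "clamp_events": int(f != f_raw) + int(p_clamped != p),
    })
    return MIDAResult(
        analyte=labeled.analyte,
        n_subunits=n_subunits,
        precursor_enrichment=p_clamped,
        fractional_synthesis=f,
        excess_distribution=EM,
        em_ratio=float(r),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# FAME masses and species-level isotopic overlap


def fame_formula(fa: LipidSpeciesName) -> ElementalFormula:
    """Methyl-ester formula of a fatty acid: FA c:d -> C(c+1) H(2(c+1)-2d) O2."""
    if fa.lipid_class != "FA":
        raise ValueError(f"{fa.raw_label!r} is not an FA species")
    c, d = fa.total_carbons, fa.total_double_bonds
    h = 2 * (c + 1) - 2 * d
    if h <= 0:
        raise ValueError(f"{fa.raw_label!r}: impossible hydrogen count")
    return ElementalFormula({"C": c + 1, "H": h, "O": 2})


def fame_nominal_mass(fa: LipidSpeciesName) -> int:
    """Nominal molecular-ion m/z of the FAME derivative (C=12, H=1, O=16).

    FA 16:0 gives C17H34O2 and m/z 270, the monitored molecular ion in
    GC-MS single-ion monitoring of palmitate.
    """
    return fame_formula(fa).nominal_mass()


@dataclass
class OverlapCorrectionRow:
    species: LipidSpeciesName
    measured: float
    corrected: float
    subtracted: float
    donor: LipidSpeciesName | None
    clamped: bool = False


@dataclass
class OverlapCorrectionReport:
    rows: list[OverlapCorrectionRow]

    def corrected_intensities(self) -> dict[str, float]:
        return {r.species.label: r.corrected for r in self.rows}

    def __iter__(self):
        return iter(self.rows)


def correct_isotopic_overlap(
    class_intensities: list[tuple[LipidSpeciesName, float, ElementalFormula]],
    *,
    a2_factors: dict[str, float] | None = None,
) -> OverlapCorrectionReport:
    """Remove M+2 isotopic overlap within one lipid class / scan mode.

    In precursor- and neutral-loss scans of a lipid class, the second
    isotopologue (M+2) of a species with one more double bond is isobaric
    with the monoisotopic peak of the species 2 Da up (same carbon count,
    one fewer double bond).  Species are sorted by ascending nominal mass
    and, iterating upward, each already-corrected donor intensity times its
    a2 factor (NA[2]/NA[0] of the donor formula) is subtracted from its +2 Da
    acceptor.  Negative corrected intensities are clamped to zero and
    flagged.  M+1 overlap cannot occur on even-carbon species grids.
    """
    seen = set()
    for sp, _, _ in class_intensities:
        if sp.label in seen:
            raise ValueError(f"duplicate species {sp.label!r}")
        seen.add(sp.label)

    order = sorted(class_intensities, key=lambda t: t[2].nominal_mass())
    by_key = {(sp.total_carbons, sp.total_double_bonds): sp.label
              for sp, _, _ in order}
    rows: dict[str, OverlapCorrectionRow] = {}
    for sp, intensity, formula in order:
        rows[sp.label] = OverlapCorrectionRow(
            species=sp, measured=float(intensity),
            corrected=float(intensity), subtracted=0.0, donor=None,
        )
    for sp, intensity, formula in order:
        row = rows[sp.label]
        # push this donor's M+2 contribution onto the species 2 Da up
        acceptor_key = (sp.total_carbons, sp.total_double_bonds - 1)
        acceptor = by_key.get(acceptor_key)
        if acceptor is not None:
            if a2_factors is not None and sp.label in a2_factors:
                a2 = a2_factors[sp.label]
            else:
                na = _na_vector(formula)
                a2 = na[2] / na[0] if len(na) > 2 else 0.0
            contribution = a2 * max(row.corrected, 0.0)
            arow = rows[acceptor]
            arow.corrected -= contribution
            arow.subtracted += contribution
            arow.donor = sp
            if arow.corrected < 0:
                arow.corrected = 0.0
                arow.clamped = True
    return OverlapCorrectionReport(rows=[rows[sp.label] for sp, _, _ in order])
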