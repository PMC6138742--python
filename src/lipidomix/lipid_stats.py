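"""Quantitative lipidomics statistics.

The analysis stage applied per lipid class and per matrix (liver or plasma):
probabilistic quotient normalization, a 50%-per-group detection filter, a
Fisher exact test for missingness bias, saturation-category sums,
Welch-t differential testing with Benjamini-Hochberg FDR control, a
two-experiment replication filter, and desaturation/elongation
product-precursor indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ConcentrationTable, LipidSpeciesName

__all__ = [
    "DifferentialResult",
    "DifferentialAnalysis",
    "SaturationSummary",
    "RatioSet",
    "VerifiedSpecies",
    "ReplicationResult",
    "quotient_normalize",
    "filter_by_detection",
    "missingness_bias_test",
    "saturation_class_sums",
    "differential_test",
    "replication_filter",
    "desaturation_elongation_indices",
    "welch_t",
    "DEFAULT_RATIOS",
]


# ---------------------------------------------------------------------------
# Quotient normalization


def _pqn_factors(block: pd.DataFrame) -> np.ndarray:
    """One probabilistic-quotient step: per-sample median ratio to the
    species-wise median reference.  Missing cells are excluded."""
    reference = block.median(axis=0, skipna=True)
    if reference.isna().all():
        raise ValueError("all reference species missing")
    quotients = block.divide(reference, axis=1)
    factors = quotients.median(axis=1, skipna=True)
    if factors.isna().any():
        bad = list(factors.index[factors.isna()])
        raise ValueError(f"samples with no quantifiable species: {bad}")
    return factors.to_numpy()


def quotient_normalize(
    table: ConcentrationTable,
    scope: str = "class",
    *,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> ConcentrationTable:
    """Probabilistic quotient (dilution) normalization per lipid-class block.

    ``scope="class"`` partitions the species by lipid class and normalizes
    each block independently (each class is measured in its own scan mode and
    carries its own dilution); ``scope="global"`` treats the table as one
    block.  The per-sample dilution factor is the fixed point of the PQN
    update: divide by the median quotient against the species-median
    reference, recompute, and repeat until the factors are unity (within
    ``tol``).  The first iteration is classical PQN; at the fixed point the
    median quotient of every sample against the block reference is exactly 1,
    which also makes the operation idempotent.

    Missing cells are excluded from all medians and stay missing.  Cumulative
    per-block factors are stored in ``table.attrs["pqn_factors"]``.
    """
    if table.n_samples < 3:
        raise ValueError("quotient normalization needs at least 3 samples")
    if scope == "global":
        blocks = {"all": list(table.values.columns)}
    elif scope == "class":
        blocks = {}
        for col, sp in zip(table.values.columns, table.species):
            blocks.setdefault(sp.lipid_class, []).append(col)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    values = table.values.copy()
    all_factors: dict[str, np.ndarray] = {}
    for name, cols in blocks.items():
        block = values[cols]
        if block.isna().all(axis=0).all():
            raise ValueError(f"block {name!r}: all reference species missing")
        cumulative = np.ones(table.n_samples)
        for _ in range(max_iter):
            try:
                f = _pqn_factors(block)
            except ValueError as exc:
                raise ValueError(f"block {name!r}: {exc}") from None
            block = block.divide(f, axis=0)
            cumulative *= f
            if np.max(np.abs(f - 1.0)) < tol:
                break
        values[cols] = block
        all_factors[name] = cumulative
    out = table.copy_with(values)
    out.attrs["pqn_factors"] = all_factors
    return out


# ---------------------------------------------------------------------------
# Detection filter and missingness bias


def filter_by_detection(
    table: ConcentrationTable,
    min_fraction: float = 0.5,
) -> tuple[ConcentrationTable, pd.DataFrame]:
    """Retain species detected in at least ``min_fraction`` of the samples of
    *every* group (boundary inclusive).

    Returns the filtered table and a frame of excluded species with their
    per-group detection fractions.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    groups = table.sample_meta["group"]
    detected = table.values.notna()
    frac = detected.groupby(groups.values).mean()  # groups x species
    keep = (frac >= min_fraction).all(axis=0)
    excluded_cols = list(keep.index[~keep])
    excluded = frac[excluded_cols].T
    excluded.index.name = "species"
    kept_cols = [c for c in table.values.columns if keep[c]]
    by_label = table.species_by_label()
    filtered = ConcentrationTable(
        values=table.values[kept_cols],
        species=[by_label[c] for c in kept_cols],
        sample_meta=table.sample_meta.copy(),
        units=table.units,
        attrs={**table.attrs, "detection_rule":
               f"detected in >= {min_fraction:.0%} of samples per group"},
    )
    return filtered, excluded


def missingness_bias_test(table: ConcentrationTable,
                          species: str) -> tuple[float, float]:
    """Fisher exact test (two-sided) for group-biased missingness.

    Builds the 2x2 table detected/missing x group for one species and
    returns ``(odds_ratio, p_value)`` with the exact hypergeometric p.
    """
    if species not in table.values.columns:
        raise KeyError(f"species {species!r} not in table")
    groups = table.sample_meta["group"]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("missingness test requires exactly two groups")
    detected = table.values[species].notna()
    contingency = np.array(
        [
            [int(detected[groups == g].sum()),
             int((~detected[groups == g]).sum())]
            for g in levels
        ]
    )
    odds, p = stats.fisher_exact(contingency, alternative="two-sided")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# Saturation sums


@dataclass
class SaturationSummary:
    """Per-sample SA/MU/PU concentration sums per lipid class.

    ``sums`` has a (lipid_class, category) column MultiIndex; missing cells
    enter the sums as zero and are counted in ``n_imputed``.
    """

    sums: pd.DataFrame
    n_imputed: int
    empty_classes: tuple[str, ...] = ()

    def totals(self) -> pd.DataFrame:
        return self.sums.T.groupby(level=0).sum().T


def saturation_class_sums(table: ConcentrationTable) -> SaturationSummary:
    """Sum concentrations by saturation category within each lipid class.

    Categories: SA (0 double bonds), MU (1), PU (>= 2).
    """
    categories = ("SA", "MU", "PU")
    class_species: dict[str, dict[str, list[str]]] = {}
    for col, sp in zip(table.values.columns, table.species):
        class_species.setdefault(sp.lipid_class, {c: [] for c in categories})
        class_species[sp.lipid_class][sp.saturation_category].append(col)
    filled = table.values.fillna(0.0)
    n_imputed = int(table.values.isna().to_numpy().sum())
    data = {}
    empty = []
    for cls, cats in sorted(class_species.items()):
        if not any(cats.values()):
            empty.append(cls)
        for cat in categories:
            cols = cats[cat]
            data[(cls, cat)] = (
                filled[cols].sum(axis=1) if cols
                else pd.Series(0.0, index=table.values.index)
            )
    sums = pd.DataFrame(data)
    sums.columns = pd.MultiIndex.from_tuples(sums.columns,
                                             names=["lipid_class", "category"])
    return SaturationSummary(sums=sums, n_imputed=n_imputed,
                             empty_classes=tuple(empty))


# ---------------------------------------------------------------------------
# Differential testing


@dataclass
class DifferentialResult:
    """Welch-t result for one species in one experiment and matrix."""

    species: LipidSpeciesName
    log2_fc: float  # SPF minus GF on log2 scale
    t_statistic: float
    df: float
    p_value: float
    fdr_adjusted_p: float
    experiment: str
    matrix: str
    n_per_group: tuple[int, int] = (0, 0)
    degenerate_variance: bool = False


@dataclass
class DifferentialAnalysis:
    """Results plus the species skipped for insufficient data."""

    results: list[DifferentialResult]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species.label for r in self.results],
                "lipid_class": [r.species.lipid_class for r in self.results],
                "log2_fc": [r.log2_fc for r in self.results],
                "t_statistic": [r.t_statistic for r in self.results],
                "df": [r.df for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "fdr_adjusted_p": [r.fdr_adjusted_p for r in self.results],
                "experiment": [r.experiment for r in self.results],
                "matrix": [r.matrix for r in self.results],
            }
        )


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, bool]:
    """Welch's unequal-variance t-test of ``b`` vs ``a`` (two-sided).

    Returns ``(t, df, p, degenerate)`` where ``t`` is positive when ``b`` has
    the larger mean.  Zero-variance cases: both groups constant and equal
    gives t = 0, p = 1; constant but unequal gives p = 0 with the degenerate
    flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(na + nb - 2), 1.0, False
        return np.inf if b.mean() > a.mean() else -np.inf, float(na + nb - 2), 0.0, True
    se2 = va / na + vb / nb
    t = (b.mean() - a.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), False


def differential_test(
    table: ConcentrationTable,
    *,
    log_transform: bool = True,
    group_order: tuple[str, str] = ("GF", "SPF"),
    by_class_fdr: bool = False,
) -> DifferentialAnalysis:
    """Per-species Welch t-test on (log2) concentrations with BH adjustment.

    The effect is ``mean(log2 second group) - mean(log2 first group)``; with
    the default order positive means higher in SPF (colonized).  Zeros are
    treated as missing before the log transform.  Species with fewer than two
    values in either group are skipped and reported.  The BH family is all
    species in the table by default; ``by_class_fdr=True`` adjusts within
    each lipid class instead.
    """
    groups = table.sample_meta["group"]
    g0, g1 = group_order
    for g in group_order:
        if g not in set(groups):
            raise ValueError(f"group {g!r} absent from table")
    experiment = str(table.sample_meta["experiment"].iloc[0])
    matrix = str(table.sample_meta["matrix"].iloc[0])
    by_label = table.species_by_label()

    rows = []
    skipped: list[tuple[str, str]] = []
    for col in table.values.columns:
        series = table.values[col]
        if log_transform:
            series = series.where(series > 0)  # zeros -> missing
        a = series[groups == g0].dropna().to_numpy()
        b = series[groups == g1].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            skipped.append((col, f"insufficient data ({len(a)} vs {len(b)})"))
            continue
        if log_transform:
            a, b = np.log2(a), np.log2(b)
        t, df, p, degenerate = welch_t(a, b)
        rows.append(
            DifferentialResult(
                species=by_label[col],
                log2_fc=float(b.mean() - a.mean()),
                t_statistic=t, df=df,
                p_value=max(p, np.nextafter(0, 1)),
                fdr_adjusted_p=np.nan,
                experiment=experiment, matrix=matrix,
                n_per_group=(len(a), len(b)),
                degenerate_variance=degenerate,
            )
        )
    if rows:
        if by_class_fdr:
            classes = {}
            for i, r in enumerate(rows):
                classes.setdefault(r.species.lipid_class, []).append(i)
            families = classes.values()
        else:
            families = [list(range(len(rows)))]
        for idx in families:
            pvals = [rows[i].p_value for i in idx]
            _, adj, _, _ = multipletests(pvals, method="fdr_bh")
            for i, q in zip(idx, adj):
                rows[i].fdr_adjusted_p = float(q)
    return DifferentialAnalysis(results=rows, skipped=skipped)


# ---------------------------------------------------------------------------
# Replication filter


@dataclass
class VerifiedSpecies:
    species: LipidSpeciesName
    matrix: str
    exp1: DifferentialResult
    exp2: DifferentialResult

    @property
    def direction(self) -> int:
        return int(np.sign(self.exp1.log2_fc))


@dataclass
class ReplicationResult:
    verified: list[VerifiedSpecies]
    unmatched: list[str] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [v.species.label for v in self.verified]

    def __len__(self) -> int:
        return len(self.verified)


def replication_filter(
    exp1: DifferentialAnalysis | list[DifferentialResult],
    exp2: DifferentialAnalysis | list[DifferentialResult],
    q: float = 0.05,
) -> ReplicationResult:
    """Cross-experiment verification of differential species.

    A species passes when its BH-adjusted p-value is below ``q`` in *both*
    experiments and the fold-change direction is the same nonzero sign in
    both.  Species present in only one experiment are excluded and listed in
    ``unmatched``.
    """
    def index(results) -> dict[tuple[str, str], DifferentialResult]:
        return {(r.species.label, r.matrix): r for r in results}

    i1, i2 = index(exp1), index(exp2)
    verified = []
    unmatched = sorted(
        {f"{k[0]} [{k[1]}]" for k in set(i1) ^ set(i2)}
    )
    for key in i1.keys() & i2.keys():
        r1, r2 = i1[key], i2[key]
        s1, s2 = np.sign(r1.log2_fc), np.sign(r2.log2_fc)
        if (r1.fdr_adjusted_p < q and r2.fdr_adjusted_p < q
                and s1 == s2 and s1 != 0):
            verified.append(VerifiedSpecies(species=r1.species, matrix=r1.matrix,
                                            exp1=r1, exp2=r2))
    verified.sort(key=lambda v: (v.matrix, v.species.label))
    return ReplicationResult(verified=verified, unmatched=unmatched)


# ---------------------------------------------------------------------------
# Desaturation / elongation indices


#: Product/precursor ratios used as enzyme-activity proxies: the
#: desaturation index tracks SCD1 (palmitate -> palmitoleate) and the
#: elongation index tracks ELOVL5 (gamma-linolenate -> dihomo-gamma-
#: linolenate).
DEFAULT_RATIOS: dict[str, tuple[str, str]] = {
    "desaturation_16": ("FA 16:1 n-7", "FA 16:0"),
    "elongation_20_3": ("FA 20:3 n-6", "FA 18:3 n-6"),
}


@dataclass
class RatioSet:
    """Per-sample named product/precursor ratios.

    ``values`` holds the ratios (NaN where undefined); ``defined`` flags
    samples with both numerator and denominator present.
    """

    values: pd.DataFrame
    defined: pd.DataFrame
    pairs: dict[str, tuple[str, str]]


def desaturation_elongation_indices(
    table: ConcentrationTable,
    ratios: dict[str, tuple[str, str]] | None = None,
) -> RatioSet:
    """Per-sample product/precursor concentration ratios.

    A missing numerator or denominator (or a zero denominator) leaves the
    ratio undefined for that sample - flagged, never coerced to zero.
    Ratios are invariant under per-sample rescaling of the table.
    """
    ratios = dict(ratios or DEFAULT_RATIOS)
    cols = set(table.values.columns)
    for name, (num, den) in ratios.items():
        for label in (num, den):
            if label not in cols:
                raise KeyError(f"ratio {name!r} references unknown species "
                               f"{label!r}")
    values = {}
    defined = {}
    for name, (num, den) in ratios.items():
        numerator = table.values[num]
        denominator = table.values[den].where(lambda s: s > 0)
        ratio = numerator / denominator
        values[name] = ratio
        defined[name] = numerator.notna() & denominator.notna()
    return RatioSet(values=pd.DataFrame(values),
                    defined=pd.DataFrame(defined), pairs=ratios)
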