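"""Core data types and tabular I/O.

Lipid species are named with the shorthand notation used in MS-based
lipidomics: a class abbreviation followed by ``<total acyl carbons>:<total
double bonds>`` (sum notation, e.g. ``PC 34:1``), optionally resolved into
individual chains separated by ``/`` (``PE P-16:0/20:4``).  Ether lipids are
flagged with an ``O-`` prefix on the chain token (``PC O-36:4``) and
plasmalogens with ``P-``.  GC-MS fatty-acid names may carry an omega-series
suffix (``FA 16:1 n-7``) which is metadata only and never enters carbon or
double-bond arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LipidNameError",
    "LipidSpeciesName",
    "parse_lipid_name",
    "ElementalFormula",
    "ConcentrationTable",
    "OmicsMatrix",
    "read_concentration_table",
    "write_results_table",
    "NA_TOKENS",
]


class LipidNameError(ValueError):
    """Raised for labels that cannot be interpreted as a lipid species."""


#: Base lipid-class abbreviations accepted by the parser.  Classes that are
#: not species-level (free cholesterol) or that never carry a c:d token are
#: deliberately absent: unknown prefixes are rejected, not guessed.
KNOWN_CLASSES = frozenset(
    {
        "FA", "PC", "LPC", "PE", "LPE", "PS", "PG", "PI", "PA", "LPA",
        "LPG", "CL", "BMP", "CE", "SM", "Cer", "HexCer", "Hex2Cer",
        "LacCer", "SPA", "SPH", "S1P", "SPC", "TAG", "DAG", "MAG",
    }
)

#: Classes on which an ether (O-) or plasmalogen (P-) variant is meaningful.
ETHER_CAPABLE = frozenset({"PC", "PE", "LPC", "LPE", "PS", "PG", "PI", "PA"})

_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")
_LABEL_RE = re.compile(
    r"^(?P<cls>[A-Za-z][A-Za-z0-9]*(?:\s?[A-Za-z0-9]+)*?)"
    r"[\s]*"
    r"(?P<ether>[OP]-)?"
    r"(?P<body>\d+:[^\s/]+(?:/\d+:[^\s/]+)*)"
    r"(?:\s+(?P<omega>n-\d+))?$"
)


@dataclass(frozen=True)
class LipidSpeciesName:
    """Parsed lipid shorthand name.

    Attributes
    ----------
    raw_label : str
        The label as supplied to the parser.
    lipid_class : str
        Class abbreviation; ether/plasmalogen variants are distinct classes
        (``"PC O"``, ``"PE P"``).
    total_carbons, total_double_bonds : int
        Sum composition of the acyl (and alkyl/alkenyl) chains.
    chains : tuple[tuple[int, int], ...] | None
        Individual ``(carbons, double_bonds)`` chains when sn-resolved.
    omega_series : str | None
        Omega-series annotation such as ``"n-7"`` (metadata only).
    """

    raw_label: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    chains: tuple[tuple[int, int], ...] | None = None
    omega_series: str | None = None

    def __post_init__(self) -> None:
        if self.lipid_class and self.total_carbons <= 0:
            raise LipidNameError(
                f"{self.raw_label!r}: total carbons must be positive"
            )
        if self.total_carbons < 0 or self.total_double_bonds < 0:
            raise LipidNameError(f"{self.raw_label!r}: negative composition")
        if self.chains is not None:
            c = sum(ch[0] for ch in self.chains)
            d = sum(ch[1] for ch in self.chains)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise LipidNameError(
                    f"{self.raw_label!r}: chain sums {c}:{d} do not match "
                    f"totals {self.total_carbons}:{self.total_double_bonds}"
                )

    @property
    def label(self) -> str:
        """Canonical serialization; ``parse_lipid_name(x.label) == x``."""
        parts = self.lipid_class.split(" ")
        base = parts[0]
        ether = parts[1] + "-" if len(parts) > 1 else ""
        if self.chains is not None:
            body = "/".join(f"{c}:{d}" for c, d in self.chains)
        else:
            body = f"{self.total_carbons}:{self.total_double_bonds}"
        sep = "" if ether else " "
        out = f"{base} {ether}{body}" if ether else f"{base}{sep}{body}"
        if self.omega_series:
            out += f" {self.omega_series}"
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @property
    def saturation_category(self) -> str:
        """``"SA"`` (0 double bonds), ``"MU"`` (1) or ``"PU"`` (>=2)."""
        d = self.total_double_bonds
        return "SA" if d == 0 else ("MU" if d == 1 else "PU")


def parse_lipid_name(label: str) -> LipidSpeciesName:
    """Parse a shorthand lipid species label.

    Parameters
    ----------
    label : str
        e.g. ``"PC 34:1"``, ``"FA 16:1 n-7"``, ``"PE P-18:0/20:4"``,
        ``"PC O-36:4"``.

    Raises
    ------
    LipidNameError
        For empty labels, unknown class prefixes, or malformed
        ``carbons:double_bonds`` tokens (the message names the fragment).
    """
    if not isinstance(label, str) or not label.strip():
        raise LipidNameError("empty name")
    text = label.strip()
    m = _LABEL_RE.match(text)
    if m is None:
        raise LipidNameError(f"cannot parse lipid label {label!r}")
    base = m.group("cls").strip()
    if base not in KNOWN_CLASSES:
        raise LipidNameError(f"unknown lipid class {base!r} in {label!r}")
    ether = m.group("ether")
    if ether:
        variant = ether[0]  # "O" or "P"
        if base not in ETHER_CAPABLE:
            raise LipidNameError(
                f"class {base!r} does not admit an {variant}- variant"
            )
        lipid_class = f"{base} {variant}"
    else:
        lipid_class = base

    tokens = m.group("body").split("/")
    chains: list[tuple[int, int]] = []
    for tok in tokens:
        cm = _CHAIN_RE.match(tok)
        if cm is None:
            raise LipidNameError(f"malformed carbon:double-bond token {tok!r}")
        chains.append((int(cm.group(1)), int(cm.group(2))))
    if len(chains) == 1:
        total_c, total_d = chains[0]
        chain_field = None
    else:
        total_c = sum(c for c, _ in chains)
        total_d = sum(d for _, d in chains)
        chain_field = tuple(chains)
    return LipidSpeciesName(
        raw_label=label,
        lipid_class=lipid_class,
        total_carbons=total_c,
        total_double_bonds=total_d,
        chains=chain_field,
        omega_series=m.group("omega"),
    )


# ---------------------------------------------------------------------------
# Elemental formulas


_ELEMENT_ORDER = ("C", "H", "N", "O", "P", "S")  # Hill: C, H, then alphabetical
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Molecular formula over C, H, O, N, P, S with non-negative counts."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in _ELEMENT_ORDER:
                raise ValueError(f"unsupported element {el!r}")
            if int(n) < 0:
                raise ValueError(f"negative atom count for {el}")
            if n:
                clean[el] = int(n)
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse Hill-notation text such as ``"C17H34O2"``."""
        text = text.strip()
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_RE.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def hill(self) -> str:
        """Hill-notation serialization (round-trips through :meth:`parse`)."""
        out = []
        for el in _ELEMENT_ORDER:
            n = self.counts.get(el, 0)
            if n:
                out.append(el if n == 1 else f"{el}{n}")
        return "".join(out)

    def __str__(self) -> str:
        return self.hill()

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def nominal_mass(self) -> int:
        """Nominal (integer) mass with C=12, H=1, N=14, O=16, P=31, S=32."""
        masses = {"C": 12, "H": 1, "N": 14, "O": 16, "P": 31, "S": 32}
        return sum(masses[el] * n for el, n in self.counts.items())


# ---------------------------------------------------------------------------
# Tabular containers


REQUIRED_SAMPLE_META = ("group", "experiment", "matrix")


@dataclass
class ConcentrationTable:
    """Samples x lipid-species concentration matrix with annotations.

    ``values`` holds concentrations with ``NaN`` marking missing cells;
    ``species`` is positionally aligned with the columns; ``sample_meta`` is
    indexed by sample id and carries at least ``group``, ``experiment`` and
    ``matrix`` columns.
    """

    values: pd.DataFrame
    species: list[LipidSpeciesName]
    sample_meta: pd.DataFrame
    units: str = "nmol/mg"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.species) != self.values.shape[1]:
            raise ValueError("species list does not match number of columns")
        if len(self.sample_meta) != self.values.shape[0]:
            raise ValueError("sample_meta does not match number of rows")
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta must share the sample index")
        for col in REQUIRED_SAMPLE_META:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing-value mask (True = missing)."""
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def species_by_label(self) -> dict[str, LipidSpeciesName]:
        return {c: sp for c, sp in zip(self.values.columns, self.species)}

    def copy_with(self, values: pd.DataFrame) -> "ConcentrationTable":
        return ConcentrationTable(
            values=values,
            species=list(self.species),
            sample_meta=self.sample_meta.copy(),
            units=self.units,
            attrs=dict(self.attrs),
        )

    def subset_samples(self, index: Sequence) -> "ConcentrationTable":
        return ConcentrationTable(
            values=self.values.loc[index],
            species=list(self.species),
            sample_meta=self.sample_meta.loc[index],
            units=self.units,
            attrs=dict(self.attrs),
        )

    def to_csv(self, path, sep: str = ",") -> None:
        out = pd.concat([self.sample_meta[list(REQUIRED_SAMPLE_META)],
                         self.values], axis=1)
        out.index.name = "sample"
        out.to_csv(path, sep=sep)


@dataclass
class OmicsMatrix:
    """Features x samples expression/intensity matrix for one omics layer."""

    values: pd.DataFrame
    feature_meta: pd.DataFrame  # index = feature id; gene_symbol, layer
    sample_meta: pd.DataFrame  # index = sample id; group, experiment
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.feature_meta.index):
            raise ValueError("values and feature_meta must share the feature index")
        if not self.values.columns.equals(self.sample_meta.index):
            raise ValueError("values columns and sample_meta must share sample ids")
        if "gene_symbol" not in self.feature_meta.columns:
            raise ValueError("feature_meta missing 'gene_symbol'")
        if "layer" not in self.feature_meta.columns:
            raise ValueError("feature_meta missing 'layer'")
        if not self.log_scale:
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("negative values in a non-log intensity matrix")

    @property
    def layer(self) -> str:
        layers = self.feature_meta["layer"].unique()
        return layers[0] if len(layers) == 1 else "mixed"

    def copy_with(self, values: pd.DataFrame, *, log_scale: bool | None = None
                  ) -> "OmicsMatrix":
        return OmicsMatrix(
            values=values,
            feature_meta=self.feature_meta.loc[values.index].copy(),
            sample_meta=self.sample_meta.copy(),
            log_scale=self.log_scale if log_scale is None else log_scale,
        )


# ---------------------------------------------------------------------------
# Readers / writers


NA_TOKENS = ("", "na", "nan")


def _is_na_token(cell: str, na_tokens: tuple[str, ...]) -> bool:
    return cell.strip().lower() in na_tokens


def read_concentration_table(
    path,
    *,
    sep: str = ",",
    na_tokens: Iterable[str] = NA_TOKENS,
    sample_col: str = "sample",
    group_col: str = "group",
    experiment_col: str = "experiment",
    matrix_col: str = "matrix",
    units: str = "nmol/mg",
) -> ConcentrationTable:
    """Read a wide-format concentration table.

    One header row of species labels plus the designated metadata columns.
    Blank cells and recognized NA tokens (case-insensitive) become missing;
    any other non-numeric cell raises with its row and column.
    """
    na_tokens = tuple(t.lower() for t in na_tokens)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if sample_col not in raw.columns:
        raise ValueError(f"missing sample id column {sample_col!r}")
    meta_cols = {sample_col, group_col, experiment_col, matrix_col}
    missing_meta = meta_cols - set(raw.columns)
    if missing_meta:
        raise ValueError(f"missing metadata columns: {sorted(missing_meta)}")

    sample_ids = raw[sample_col].astype(str)
    dup = sample_ids[sample_ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")

    species_cols = [c for c in raw.columns if c not in meta_cols]
    species = [parse_lipid_name(c) for c in species_cols]

    data = np.full((len(raw), len(species_cols)), np.nan)
    for j, col in enumerate(species_cols):
        for i, cell in enumerate(raw[col]):
            if _is_na_token(cell, na_tokens):
                continue
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {i + 2}, column {col!r}"
                ) from None

    values = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample"),
                          columns=species_cols)
    sample_meta = pd.DataFrame(
        {
            "group": raw[group_col].values,
            "experiment": raw[experiment_col].values,
            "matrix": raw[matrix_col].values,
        },
        index=values.index,
    )
    return ConcentrationTable(values=values, species=species,
                              sample_meta=sample_meta, units=units)


def write_results_table(records, path, *, sep: str = ",",
                        sig_digits: int = 8) -> None:
    """Write any tabular result set to CSV with deterministic column order.

    ``records`` may be a DataFrame, a sequence of mappings, or a sequence of
    dataclasses; floats are serialized with ``sig_digits`` significant digits
    (8 by default, so a write/read round trip agrees to 1e-6 relative).
    """
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                rows.append({f: getattr(rec, f) for f in rec.__dataclass_fields__})
            else:
                rows.append(dict(rec))
        frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("refusing to write an empty record set")
    path = Path(path)
    frame.to_csv(path, sep=sep, index=False,
                 float_format=f"%.{sig_digits}g", encoding="utf-8")
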