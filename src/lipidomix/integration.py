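"""Cross-layer omics integration and pathway-reconstruction correlations.

Transcript, protein and phosphopeptide matrices are preprocessed
(total-intensity normalization, per-feature minimum imputation, log2),
tested per feature (Welch t + BH), merged on the gene symbol with an
interquartile-range tie-break, and compared between layers as concordance
quadrants of directed p-values.  Product/precursor lipid ratios are
correlated against the expression of the enzymes that produce them
(e.g. Scd1 vs the 16:1 n-7 / 16:0 desaturation index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import OmicsMatrix
from .lipid_stats import RatioSet, welch_t

__all__ = [
    "MergedGeneRecord",
    "QuadrantAssignment",
    "CorrelationResult",
    "normalize_total_intensity",
    "impute_min_per_feature",
    "omics_differential_test",
    "merge_layers_by_gene",
    "directed_pvalue",
    "quadrant_partition",
    "ratio_expression_correlation",
]


# ---------------------------------------------------------------------------
# Preprocessing


def normalize_total_intensity(m: OmicsMatrix) -> OmicsMatrix:
    """Scale each sample so its total intensity equals the across-sample
    mean of the original totals."""
    if m.log_scale:
        raise ValueError("total-intensity normalization expects raw intensities")
    totals = m.values.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total intensity: {bad}")
    target = totals.mean()
    return m.copy_with(m.values.divide(totals, axis=1) * target)


def impute_min_per_feature(
    m: OmicsMatrix, *, log2: bool = False
) -> tuple[OmicsMatrix, list[str]]:
    """Replace missing cells with the feature's observed minimum.

    Features with no observed value are dropped and returned in the report
    list.  With ``log2=True`` the imputed matrix is log2-transformed (the
    standard next step so intensities are approximately normal).
    """
    observed_min = m.values.min(axis=1, skipna=True)
    dropped = list(m.values.index[observed_min.isna()])
    kept = m.values.drop(index=dropped)
    filled = kept.T.fillna(observed_min.drop(dropped)).T
    out = m.copy_with(filled)
    if log2:
        if (filled <= 0).any().any():
            raise ValueError("log2 transform requires positive intensities")
        out = out.copy_with(np.log2(filled), log_scale=True)
    return out, dropped


def omics_differential_test(
    m: OmicsMatrix,
    *,
    group_order: tuple[str, str] = ("GF", "SPF"),
) -> pd.DataFrame:
    """Per-feature Welch t-test with BH adjustment on a log2 matrix.

    Returns a frame indexed by feature id with ``effect`` (mean difference,
    second group minus first; log2 fold change on a log2 matrix), ``p_value``
    and ``fdr_adjusted_p``.
    """
    if not m.log_scale:
        raise ValueError("differential testing expects a log2 matrix; "
                         "preprocess first")
    groups = m.sample_meta["group"]
    g0, g1 = group_order
    a_cols = list(groups.index[groups == g0])
    b_cols = list(groups.index[groups == g1])
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least two samples")
    effects, pvals = [], []
    for _, row in m.values.iterrows():
        a = row[a_cols].dropna().to_numpy()
        b = row[b_cols].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            effects.append(np.nan)
            pvals.append(np.nan)
            continue
        t, df, p, _ = welch_t(a, b)
        effects.append(b.mean() - a.mean())
        pvals.append(max(p, np.nextafter(0, 1)))
    frame = pd.DataFrame(
        {"effect": effects, "p_value": pvals}, index=m.values.index
    )
    ok = frame["p_value"].notna()
    adj = pd.Series(np.nan, index=frame.index)
    if ok.any():
        _, q, _, _ = multipletests(frame.loc[ok, "p_value"], method="fdr_bh")
        adj[ok] = q
    frame["fdr_adjusted_p"] = adj
    return frame


# ---------------------------------------------------------------------------
# Gene-symbol merge with IQR tie-break


@dataclass
class MergedGeneRecord:
    """Per-gene aligned statistics across omics layers.

    ``layers`` maps layer name to a dict with ``feature_id``, ``effect``,
    ``p_value``, ``fdr_adjusted_p`` and ``iqr`` of the chosen feature (the
    duplicate with the highest interquartile range wins).
    """

    gene_symbol: str
    layers: dict[str, dict] = field(default_factory=dict)

    def effect(self, layer: str) -> float:
        return self.layers[layer]["effect"]

    def p_value(self, layer: str) -> float:
        return self.layers[layer]["p_value"]


def _normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def merge_layers_by_gene(
    layers: list[tuple[OmicsMatrix, pd.DataFrame]],
) -> list[MergedGeneRecord]:
    """Inner-join omics layers on the case-normalized gene symbol.

    Each entry pairs a (normalized, log2) matrix with its per-feature
    differential frame (as from :func:`omics_differential_test`).  When
    several features map to one gene, the feature with the highest IQR on
    the matrix wins.  Raises when the gene intersection is empty.  The merge
    is idempotent and independent of the layer order.
    """
    per_layer: list[tuple[str, dict[str, dict]]] = []
    for m, diff in layers:
        iqr = m.values.apply(
            lambda row: stats.iqr(row.dropna()) if row.notna().sum() else 0.0,
            axis=1,
        )
        chosen: dict[str, dict] = {}
        for fid in m.values.index:
            sym = _normalize_symbol(m.feature_meta.loc[fid, "gene_symbol"])
            if not sym or sym == "NAN":
                continue
            rec = {
                "feature_id": fid,
                "iqr": float(iqr[fid]),
                "effect": float(diff.loc[fid, "effect"]),
                "p_value": float(diff.loc[fid, "p_value"]),
                "fdr_adjusted_p": float(diff.loc[fid, "fdr_adjusted_p"]),
            }
            if sym not in chosen or rec["iqr"] > chosen[sym]["iqr"]:
                chosen[sym] = rec
        per_layer.append((m.layer, chosen))

    common = set.intersection(*(set(c) for _, c in per_layer))
    if not common:
        raise ValueError("no genes shared across the requested layers")
    records = []
    for sym in sorted(common):
        records.append(
            MergedGeneRecord(
                gene_symbol=sym,
                layers={name: dict(chosen[sym]) for name, chosen in per_layer},
            )
        )
    return records


# ---------------------------------------------------------------------------
# Directed p-values and quadrants


def directed_pvalue(p: float, effect_sign: int) -> float:
    """Signed significance: ``-log10(p)`` times the effect direction."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if effect_sign not in (-1, 0, 1):
        raise ValueError("effect_sign must be -1, 0 or +1")
    return float(-np.log10(p) * effect_sign)


@dataclass
class QuadrantAssignment:
    gene_symbol: str
    quadrant: str | None  # Q1..Q4, or None for a zero effect
    directed_p_x: float
    directed_p_y: float
    significant_x: bool
    significant_y: bool


def quadrant_partition(
    records: list[MergedGeneRecord],
    x_layer: str,
    y_layer: str,
    *,
    alpha: float = 0.05,
) -> tuple[list[QuadrantAssignment], dict]:
    """Partition merged genes into concordance quadrants.

    Semantics (positive = higher in the colonized/SPF group on both axes):
    Q2 = concordant up, Q4 = concordant down, Q1 = x down / y up,
    Q3 = x up / y down.  Genes with a zero effect on either axis are
    unassigned and counted separately, so quadrant counts plus the
    zero-effect count always equal the number of merged genes.  The counts
    dict also reports the co-regulated fraction (Q2 + Q4) / total and the
    per-quadrant doubly-significant (both BH-adjusted p < ``alpha``) counts.
    """
    assignments = []
    counts = {q: 0 for q in ("Q1", "Q2", "Q3", "Q4")}
    sig_counts = {q: 0 for q in ("Q1", "Q2", "Q3", "Q4")}
    zero = 0
    for rec in records:
        ex, ey = rec.effect(x_layer), rec.effect(y_layer)
        sx, sy = int(np.sign(ex)), int(np.sign(ey))
        if sx == 0 or sy == 0:
            quadrant = None
            zero += 1
        elif sx > 0 and sy > 0:
            quadrant = "Q2"
        elif sx < 0 and sy < 0:
            quadrant = "Q4"
        elif sx < 0:
            quadrant = "Q1"
        else:
            quadrant = "Q3"
        sig_x = rec.layers[x_layer]["fdr_adjusted_p"] < alpha
        sig_y = rec.layers[y_layer]["fdr_adjusted_p"] < alpha
        if quadrant:
            counts[quadrant] += 1
            if sig_x and sig_y:
                sig_counts[quadrant] += 1
        assignments.append(
            QuadrantAssignment(
                gene_symbol=rec.gene_symbol,
                quadrant=quadrant,
                directed_p_x=directed_pvalue(rec.p_value(x_layer), sx),
                directed_p_y=directed_pvalue(rec.p_value(y_layer), sy),
                significant_x=bool(sig_x),
                significant_y=bool(sig_y),
            )
        )
    total = len(records)
    summary = {
        **counts,
        "zero_effect": zero,
        "total": total,
        "co_regulated_fraction": (counts["Q2"] + counts["Q4"]) / total
        if total else np.nan,
        "doubly_significant": sig_counts,
        "axes": {"x": x_layer, "y": y_layer},
    }
    return assignments, summary


# ---------------------------------------------------------------------------
# Ratio-expression correlation


@dataclass
class CorrelationResult:
    pair: str
    gene_symbol: str
    ratio_name: str
    method: str
    r: float
    p_value: float
    n: int


def ratio_expression_correlation(
    ratios: RatioSet,
    expression: OmicsMatrix,
    pairs: list[tuple[str, str]],
    *,
    methods: tuple[str, ...] = ("pearson",),
) -> list[CorrelationResult]:
    """Correlate product/precursor ratios with enzyme expression.

    ``pairs`` lists (gene symbol, ratio name); samples are aligned by id and
    only complete pairs enter.  Fewer than 3 complete pairs is an error.
    """
    sym_to_feature: dict[str, str] = {}
    for fid in expression.values.index:
        sym = _normalize_symbol(expression.feature_meta.loc[fid, "gene_symbol"])
        sym_to_feature.setdefault(sym, fid)
    results = []
    for gene, ratio_name in pairs:
        if ratio_name not in ratios.values.columns:
            raise KeyError(f"unknown ratio {ratio_name!r}")
        fid = sym_to_feature.get(_normalize_symbol(gene))
        if fid is None:
            raise KeyError(f"gene {gene!r} not found in expression matrix")
        expr = expression.values.loc[fid]
        ratio = ratios.values[ratio_name]
        shared = expr.index.intersection(ratio.index)
        aligned = pd.DataFrame({"expr": expr[shared], "ratio": ratio[shared]}).dropna()
        if len(aligned) < 3:
            raise ValueError(
                f"pair ({gene}, {ratio_name}): fewer than 3 complete pairs"
            )
        for method in methods:
            if method == "pearson":
                r, p = stats.pearsonr(aligned["expr"], aligned["ratio"])
            elif method == "spearman":
                r, p = stats.spearmanr(aligned["expr"], aligned["ratio"])
            else:
                raise ValueError(f"unknown method {method!r}")
            results.append(
                CorrelationResult(
                    pair=f"{gene} vs {ratio_name}",
                    gene_symbol=gene, ratio_name=ratio_name,
                    method=method, r=float(r), p_value=float(p),
                    n=len(aligned),
                )
            )
    return results
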