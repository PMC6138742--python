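"""Bundled reference panel of verified lipid species.

Two independent germfree (GF) vs specific-pathogen-free (SPF) mouse cohorts
(experiment 1: n = 6/6; experiment 2: GF n = 12, SPF n = 14) were profiled
for liver and plasma lipid species.  A species counts as *verified* when it
is significant in both experiments and the log2 fold change (SPF minus GF)
points the same way in both.  The panel below lists every verified species
with its per-experiment log2 fold change and p-value; it doubles as the
canonical fixture for the shorthand-name parser and the replication filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import parse_lipid_name

__all__ = ["VERIFIED_SPECIES", "verified_species_frame",
           "replication_direction_counts"]

# (species, lipid class, matrix, log2 FC exp1, log2 FC exp2, p exp1, p exp2)
VERIFIED_SPECIES: tuple[tuple[str, str, str, float, float, float, float], ...] = (
    ("FA 16:1 n-7", "FA", "liver", 1.39, 0.31, 0.014, 0.019),
    ("FA 20:3 n-6", "FA", "liver", 0.48, 0.18, 0.003, 0.039),
    ("FA 22:6 n-3", "FA", "liver", -0.40, -0.18, 0.011, 0.011),
    ("FA 16:1 n-7", "FA", "plasma", 1.41, 0.36, 0.013, 0.014),
    ("FA 20:4 n-6", "FA", "plasma", -1.09, -0.41, 0.021, 0.039),
    ("PC 32:0", "PC", "liver", -0.36, -0.22, 0.006, 0.018),
    ("PC 34:1", "PC", "liver", 0.98, 0.34, 0.009, 0.029),
    ("PC 36:1", "PC", "liver", 0.89, 0.33, 0.014, 0.002),
    ("PC 38:2", "PC", "liver", 1.47, 0.52, 0.019, 0.001),
    ("PC 38:3", "PC", "liver", 0.61, 0.36, 0.011, 0.002),
    ("PC O-36:1", "PC O", "liver", 0.56, 0.18, 0.006, 0.010),
    ("PC O-36:4", "PC O", "liver", -0.55, -0.24, 0.030, 0.017),
    ("PC 34:1", "PC", "plasma", 1.17, 0.35, 0.004, 0.004),
    ("PC 38:3", "PC", "plasma", 0.55, 0.17, 0.024, 0.006),
    ("PC O-38:4", "PC O", "plasma", -0.60, -0.36, 0.017, 0.014),
    ("LPC 20:3", "LPC", "liver", 1.18, 0.47, 0.005, 0.002),
    ("LPC 20:3", "LPC", "plasma", 1.14, 0.30, 0.006, 0.000),
    ("PE 32:0", "PE", "liver", -0.41, -0.55, 0.041, 0.001),
    ("PE 38:5", "PE", "plasma", 0.31, 0.21, 0.030, 0.039),
    ("PE P-18:0/20:4", "PE P", "liver", -0.50, -0.17, 0.011, 0.021),
    ("PE P-16:0/20:4", "PE P", "plasma", -0.91, -0.32, 0.013, 0.003),
    ("PE P-16:0/22:6", "PE P", "plasma", -1.20, -0.45, 0.010, 0.004),
    ("PE P-18:0/20:4", "PE P", "plasma", -0.95, -0.26, 0.032, 0.039),
    ("PE P-18:0/22:6", "PE P", "plasma", -1.33, -0.45, 0.029, 0.003),
    ("PI 36:2", "PI", "liver", -1.16, -0.91, 0.001, 0.000),
    ("PI 40:6", "PI", "liver", -0.92, -0.88, 0.005, 0.000),
    ("PI 36:4", "PI", "plasma", 0.23, 0.38, 0.038, 0.000),
    ("PI 40:6", "PI", "plasma", -0.75, -0.76, 0.003, 0.000),
    ("CE 20:4", "CE", "liver", -0.65, -0.29, 0.014, 0.007),
    ("CE 20:3", "CE", "plasma", 0.95, 0.32, 0.017, 0.018),
    ("CE 20:4", "CE", "plasma", -0.72, -0.35, 0.017, 0.006),
)


def verified_species_frame() -> pd.DataFrame:
    """The verified-species panel as a DataFrame (one row per species/matrix).

    Every species label in the panel parses through
    :func:`lipidomix.datamodel.parse_lipid_name`; the parsed class is checked
    against the annotated class.
    """
    frame = pd.DataFrame(
        list(VERIFIED_SPECIES),
        columns=["species", "lipid_class", "matrix",
                 "log2_fc_exp1", "log2_fc_exp2", "p_exp1", "p_exp2"],
    )
    parsed_classes = [parse_lipid_name(s).lipid_class for s in frame["species"]]
    if list(frame["lipid_class"]) != parsed_classes:
        raise AssertionError("bundled panel inconsistent with parser")
    return frame


def replication_direction_counts(frame: pd.DataFrame | None = None,
                                 alpha: float = 0.05) -> dict[str, int]:
    """Count species per matrix that replicate across the two cohorts.

    A species counts when both experiments are significant at ``alpha`` and
    the fold-change direction agrees (same nonzero sign).  Printed p-values
    of 0.000 are rounded-down representations of p < 0.0005 and pass any
    reasonable ``alpha``.
    """
    if frame is None:
        frame = verified_species_frame()
    sign_ok = (np.sign(frame["log2_fc_exp1"]) == np.sign(frame["log2_fc_exp2"])) & (
        np.sign(frame["log2_fc_exp1"]) != 0
    )
    sig_ok = (frame["p_exp1"] < alpha) & (frame["p_exp2"] < alpha)
    passed = frame[sign_ok & sig_ok]
    return passed.groupby("matrix")["species"].count().to_dict()
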