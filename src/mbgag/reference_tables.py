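"""Published reference tables for the MB-GAG dp10 systems.

These printed values are inputs to the package: the MM-GBSA component
bookkeeping checks reproduce the per-drug columns and the additivity
identity from them, and the scripted-trajectory scenarios use the binding
rows (n_MB, t) and contact percentages as scheduled ground truth.  Energies
are kcal/mol, contact values percent of simulation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ENERGY_TABLE",
    "BINDING_TABLE",
    "CONTACT_TABLE",
    "BindingRow",
    "SPACING_ANGSTROM",
]

#: observed inter-plane spacing of adjacent stacked MB molecules
SPACING_ANGSTROM = 3.7

# MM-GBSA binding free energy components per system, with the published
# per-drug normalizations alongside the raw totals.
ENERGY_TABLE = pd.DataFrame(
    [
        # system, n_drugs, dG, dG/n, vdw, vdw/n, eel, eel/n,
        #   esurf, esurf/n, eel+egb, (eel+egb)/n
        ("MB-MB", 2, -13.0, -6.5, -15.1, -7.5, 44.6, 22.3,
         -1.0, -0.5, 3.1, 1.5),
        ("HP", 10, -55.0, -5.5, -44.6, -4.5, -3263.4, -326.3,
         -5.1, -0.5, -5.4, -0.5),
        ("deHP", 7, -2.8, -0.3, 0.0, 0.0, -174.1, -17.4,
         0.0, 0.0, -2.1, -0.2),
        ("CS4", 10, -43.6, -4.4, -45.7, -4.6, -1679.2, -167.9,
         -4.2, -0.4, 6.4, 0.6),
        ("CS6", 10, -50.0, -5.0, -50.5, -5.1, -1861.6, -186.2,
         -5.0, -0.5, 5.6, 0.6),
        ("HS1", 10, -29.9, -3.0, -22.4, -2.2, -2209.2, -220.9,
         -3.1, -0.3, -4.5, -0.5),
        ("HS2", 10, -55.5, -5.6, -55.2, -5.5, -2322.3, -232.2,
         -5.4, -0.5, 5.0, 0.5),
        ("HS3", 10, -20.3, -2.0, -11.3, -1.1, -1639.1, -163.9,
         -1.4, -0.1, -7.6, -0.8),
    ],
    columns=[
        "system", "n_drugs",
        "dg", "dg_per_drug",
        "vdw", "vdw_per_drug",
        "eel", "eel_per_drug",
        "esurf", "esurf_per_drug",
        "eel_plus_egb", "eel_plus_egb_per_drug",
    ],
)


@dataclass(frozen=True)
class BindingRow:
    n_mb: int
    n_so3: int
    t: float | None  # fraction of simulation time; None where unreported
    d: float | None  # sulfation-dependence statistic; None where undefined


#: simultaneous-binder counts, time fractions and the D statistic per preset
BINDING_TABLE: dict[str, BindingRow] = {
    "HP": BindingRow(10, 15, 0.42, 0.28),
    "deHP": BindingRow(7, 0, None, None),
    "CS4": BindingRow(10, 5, 0.30, 0.60),
    "CS6": BindingRow(10, 5, 0.50, 1.00),
    "HS1": BindingRow(10, 10, 0.30, 0.30),
    "HS2": BindingRow(10, 10, 0.50, 0.50),
    "HS3": BindingRow(10, 10, 0.10, 0.10),
}

#: contact time fractions (percent) per preset and site type; None where the
#: preset has no such sites
CONTACT_TABLE: dict[str, dict[str, float | None]] = {
    "HP": {"N-sulfate": 29.7, "4-O-sulfate": None, "6-O-sulfate": 20.3,
           "2-O-sulfate": 22.0, "carboxylate": 23.6},
    "deHP": {"N-sulfate": None, "4-O-sulfate": None, "6-O-sulfate": None,
             "2-O-sulfate": None, "carboxylate": 13.4},
    "CS4": {"N-sulfate": None, "4-O-sulfate": 30.2, "6-O-sulfate": None,
            "2-O-sulfate": None, "carboxylate": 21.1},
    "CS6": {"N-sulfate": None, "4-O-sulfate": None, "6-O-sulfate": 28.4,
            "2-O-sulfate": None, "carboxylate": 29.1},
    "HS1": {"N-sulfate": 29.9, "4-O-sulfate": None, "6-O-sulfate": None,
            "2-O-sulfate": 31.5, "carboxylate": 25.9},
    "HS2": {"N-sulfate": 19.3, "4-O-sulfate": None, "6-O-sulfate": 31.6,
            "2-O-sulfate": None, "carboxylate": 30.1},
    "HS3": {"N-sulfate": None, "4-O-sulfate": None, "6-O-sulfate": 28.4,
            "2-O-sulfate": 23.0, "carboxylate": 1.6},
}
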