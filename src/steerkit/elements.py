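"""Per-element constants used by clash criteria.

Van der Waals radii follow the consolidated Bondi/Mantina set (Å) that most
structure-validation tools ship. Elements absent from the table fall back to
a generic 2.0 Å radius.
"""

from __future__ import annotations

VDW_RADII: dict[str, float] = {
    "H": 1.10,
    "HE": 1.40,
    "LI": 1.81,
    "BE": 1.53,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NE": 1.54,
    "NA": 2.27,
    "MG": 1.73,
    "AL": 1.84,
    "SI": 2.10,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "AR": 1.88,
    "K": 2.75,
    "CA": 2.31,
    "MN": 2.05,
    "FE": 2.04,
    "CO": 2.00,
    "NI": 1.97,
    "CU": 1.96,
    "ZN": 2.01,
    "GA": 1.87,
    "GE": 2.11,
    "AS": 1.85,
    "SE": 1.90,
    "BR": 1.85,
    "KR": 2.02,
    "RB": 3.03,
    "SR": 2.49,
    "MO": 2.10,
    "RU": 2.05,
    "PD": 2.10,
    "AG": 2.11,
    "CD": 2.18,
    "SN": 2.17,
    "SB": 2.06,
    "TE": 2.06,
    "I": 1.98,
    "XE": 2.16,
    "CS": 3.43,
    "BA": 2.68,
    "W": 2.10,
    "PT": 2.05,
    "AU": 2.13,
    "HG": 2.23,
    "PB": 2.02,
}

DEFAULT_VDW_RADIUS = 2.0


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Å for an element symbol (case-insensitive)."""
    return VDW_RADII.get(element.strip().upper(), DEFAULT_VDW_RADIUS)
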