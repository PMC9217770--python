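"""Published cohort summary statistics used as inputs.

These are the printed group-level numbers of the clinical comparison this
package re-analyses: per-organ EAR mean +/- SD for the three treatment
groups of 11 patients each (plus the conventional-linac PBI group with daily
CBCT dose added), the published adjusted p-value cells, the contralateral
breast maximum-dose summaries and the PTV volume summaries.  They serve two
purposes: calibration targets for the synthetic cohort and inputs to the
summary-statistics reproduction of the comparison table.  Nothing here is a
computed result of this package.
"""

from __future__ import annotations

__all__ = [
    "N_PER_GROUP",
    "EAR_SUMMARIES",
    "ADJUSTED_P_PRINTED",
    "COMPARISON_COLUMNS",
    "DMAX_BREAST_CONTRALATERAL",
    "PTV_VOLUME_CM3",
    "MEAN_IPSILATERAL_LUNG_EAR",
]

N_PER_GROUP = 11

#: organ -> group -> (mean EAR, sample SD), per 10,000 person-years.
EAR_SUMMARIES = {
    "breast_contralateral": {
        "PBI_CTL": (1.408, 0.413),
        "PBI_MRL": (0.894, 0.241),
        "WBI_CTL": (1.16, 0.306),
        "PBI_CTL_CBCT": (2.222, 0.454),
    },
    "lungs_both": {
        "PBI_CTL": (8.6351, 1.656),
        "PBI_MRL": (7.912, 2.497),
        "WBI_CTL": (8.391, 0.958),
        "PBI_CTL_CBCT": (11.372, 1.112),
    },
    "lung_ipsilateral": {
        "PBI_CTL": (12.441, 2.276),
        "PBI_MRL": (12.423, 3.987),
        "WBI_CTL": (13.064, 1.01),
        "PBI_CTL_CBCT": (15.207, 1.715),
    },
    "lung_contralateral": {
        "PBI_CTL": (4.432, 1.463),
        "PBI_MRL": (3.226, 0.907),
        "WBI_CTL": (3.92, 1.241),
        "PBI_CTL_CBCT": (7.104, 1.042),
    },
    "thyroid": {
        "PBI_CTL": (0.168, 0.136),
        "PBI_MRL": (0.326, 0.11),
        "WBI_CTL": (0.461, 0.187),
        "PBI_CTL_CBCT": (0.529, 0.268),
    },
    "esophagus": {
        "PBI_CTL": (0.774, 0.203),
        "PBI_MRL": (0.863, 0.275),
        "WBI_CTL": (1.011, 0.229),
        "PBI_CTL_CBCT": (1.286, 0.099),
    },
}

#: Comparison columns in print order (group_a vs group_b).
COMPARISON_COLUMNS = (
    ("PBI_CTL", "PBI_MRL"),
    ("PBI_CTL", "WBI_CTL"),
    ("WBI_CTL", "PBI_MRL"),
    ("PBI_CTL_CBCT", "PBI_MRL"),
)

#: organ -> printed adjusted p-values per comparison column, as printed
#: (strings preserve the printed precision; "<0.0001" cells are bounds).
ADJUSTED_P_PRINTED = {
    "breast_contralateral": ("0.01", "0.507", "0.142", "<0.0001"),
    "lungs_both": ("1.737", "2.714", "2.249", "0.004"),
    "lung_ipsilateral": ("3.96", "1.681", "2.46", "0.213"),
    "lung_contralateral": ("0.132", "1.547", "0.606", "<0.0001"),
    "thyroid": ("0.029", "0.002", "0.219", "0.177"),
    "esophagus": ("1.605", "0.074", "0.736", "0.002"),
}

#: group -> (mean, low, high) of the contralateral-breast maximum dose, Gy.
DMAX_BREAST_CONTRALATERAL = {
    "PBI_MRL": (2.86, 1.0, 10.4),
    "PBI_CTL": (3.7, 1.9, 7.7),
    "WBI_CTL": (9.06, 2.6, 19.8),
}

#: group -> (mean, low, high) planning target volume, cm^3 (PBI groups only).
PTV_VOLUME_CM3 = {
    "PBI_MRL": (265.3, 83.5, 539.6),
    "PBI_CTL": (299.0, 82.2, 615.0),
}

#: group -> published mean ipsilateral-lung EAR.
MEAN_IPSILATERAL_LUNG_EAR = {"PBI_MRL": 12.4, "PBI_CTL": 12.4, "WBI_CTL": 13.1}
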