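"""Published national summary estimates for India, 2019 (air-pollution burden
and output-loss study), kept as a fixture for arithmetic consistency checks.

Only numbers printed in the published summary tables appear here; derived
constants (national GDP, population) are back-solved at run time from printed
pairs, never hard-coded.
"""

from __future__ import annotations

# deaths (millions) and DALYs (millions) attributable to each risk, plus the
# printed national totals they are expressed against
TOTAL_DEATHS_MILLIONS = 9.39
TOTAL_DALYS_MILLIONS = 467.8

DEATHS_MILLIONS = {
    "air_pollution": 1.67,
    "ambient_pm": 0.98,
    "hap": 0.61,
    "ozone": 0.17,
}
DEATH_SHARE_PCT = {
    "air_pollution": 17.8,
    "ambient_pm": 10.4,
    "hap": 6.5,
    "ozone": 1.8,
}
DALYS_MILLIONS = {
    "air_pollution": 53.5,
    "ambient_pm": 31.1,
    "hap": 20.9,
    "ozone": 3.06,
}
DALY_SHARE_PCT = {
    "air_pollution": 11.5,
    "ambient_pm": 6.7,
    "hap": 4.5,
    "ozone": 0.7,
}

# national economic loss, US$ millions
MORTALITY_LOSS_MUSD = 28_799.0
MORBIDITY_LOSS_MUSD = 8_005.0
TOTAL_LOSS_MUSD = 36_804.0
TOTAL_LOSS_PCT_GDP = 1.36
PER_CAPITA_LOSS_USD = 26.5

# discount-rate sensitivity of the %-of-GDP loss
SENSITIVITY_PCT_GDP = {0.04: 1.86, 0.06: 1.36, 0.08: 1.10}

# cause decomposition of attributable DALYs (%) and of the economic loss (%)
DALY_CAUSE_SHARE_PCT = {
    "copd": 22.7,
    "lri": 15.5,
    "lung_cancer": 1.3,
    "ihd": 24.9,
    "stroke": 13.7,
    "diabetes": 5.5,
    "neonatal": 14.5,
    "cataract": 1.5,
}
LUNG_DISEASE_DALY_SHARE_PCT = 39.5
LOSS_CAUSE_SHARE_PCT = {
    "lung_diseases": 36.6,
    "ihd": 24.9,
    "stroke": 14.1,
    "diabetes": 8.4,
    "neonatal": 13.3,
    "cataract": 2.7,
}

# state extremes as printed
PM25_STATE_MIN = 15.8  # μg/m³
PM25_STATE_MAX = 217.6
PM25_EXTREMES_RATIO = 13.8
PCT_GDP_STATE_MIN = 0.67
PCT_GDP_STATE_MAX = 2.15
PCT_GDP_EXTREMES_RATIO = 3.2
PER_CAPITA_EXTREMES_RATIO = 5.4

# correlation of crude household-risk DALY rates with state per-capita GDP
HAP_DALY_GDP_CORRELATION_R = -0.71
HAP_DALY_GDP_CORRELATION_R2 = 0.50

# crude health-care cost check: total health spending × DALY share
HEALTHCARE_TOTAL_BUSD = 103.7
AIR_POLLUTION_DALY_FRACTION = 0.115
HEALTHCARE_ATTRIB_BUSD = 11.9

# per-state loss table: (state, mortality M$, morbidity M$, total M$, per-capita $)
STATE_LOSS_TABLE: list[tuple[str, float, float, float, float]] = [
    ("Bihar", 1257, 296, 1553, 12.7),
    ("Uttar Pradesh", 4255, 876, 5130, 21.1),
    ("Manipur", 30, 11, 40, 11.5),
    ("Jharkhand", 408, 136, 543, 14.3),
    ("Madhya Pradesh", 1614, 356, 1970, 22.2),
    ("Assam", 528, 129, 657, 18.2),
    ("Meghalaya", 30, 9, 39, 11.5),
    ("Jammu & Kashmir and Ladakh", 201, 51, 252, 18.0),
    ("Chhattisgarh", 549, 141, 690, 21.8),
    ("West Bengal", 1607, 519, 2125, 21.3),
    ("Nagaland", 26, 8, 34, 17.2),
    ("Odisha", 609, 197, 807, 17.3),
    ("Rajasthan", 1902, 392, 2294, 28.5),
    ("Tripura", 70, 21, 91, 22.6),
    ("Arunachal Pradesh", 19, 7, 26, 15.1),
    ("Mizoram", 17, 6, 22, 17.6),
    ("Andhra Pradesh", 1007, 342, 1349, 24.9),
    ("Punjab", 920, 229, 1149, 37.0),
    ("Tamil Nadu", 1886, 643, 2529, 31.7),
    ("Maharashtra", 3003, 972, 3975, 31.9),
    ("Telangana", 841, 275, 1116, 28.7),
    ("Kerala", 741, 349, 1091, 31.2),
    ("Himachal Pradesh", 192, 62, 254, 33.3),
    ("Karnataka", 2113, 568, 2681, 39.4),
    ("Uttarakhand", 413, 114, 527, 44.5),
    ("Gujarat", 2288, 571, 2860, 41.3),
    ("Haryana", 1224, 342, 1566, 53.8),
    ("Other small union territories", 86, 35, 120, 31.7),
    ("Sikkim", 17, 8, 25, 38.6),
    ("Delhi", 893, 314, 1207, 62.0),
    ("Goa", 54, 26, 80, 52.2),
]

# extreme printed per-capita losses (Delhi highest; Manipur/Meghalaya lowest)
PER_CAPITA_STATE_MAX = 62.0
PER_CAPITA_STATE_MIN = 11.5


def implied_national_gdp_musd() -> float:
    """National GDP back-solved from the printed loss and %-of-GDP pair."""
    return TOTAL_LOSS_MUSD / (TOTAL_LOSS_PCT_GDP / 100.0)


def implied_state_populations() -> dict[str, float]:
    """State populations back-solved from printed total and per-capita losses."""
    return {row[0]: row[3] * 1e6 / row[4] for row in STATE_LOSS_TABLE}
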