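"""Published summary statistics from a six-population AFLP survey of
*Acacia aroma* (Chaco region, NW Argentina; 170 adults, 401 neutral loci).

The raw band matrix of that survey was never deposited, but its printed
summary tables are fully specified arithmetic inputs: the per-population
diversity table, and the fine-scale SGS table of first-class kinship F_1,
log-distance regression slope b_F, neighbourhood size N_b and census density
D_E (trees/ha).  They are bundled here so worked examples and validation
checks can recompute Sp = -b_F/(1 - F_1) and
sigma_g = sqrt(N_b/(4*pi*D_E)) from printed inputs.

QUA/QUB are the two spatial subgroups of the patchily distributed QU stand.
sigma_g columns correspond to effective densities D_E, D_E/2, D_E/4, D_E/10.
"""

import pandas as pd

#: Diversity table: sample size, % polymorphic loci, expected heterozygosity.
DIVERSITY = pd.DataFrame(
    [
        ("LA", 50, 60.3, 0.21, 0.01),
        ("MI", 20, 60.6, 0.21, 0.01),
        ("QU", 50, 67.1, 0.23, 0.01),
        ("RO", 22, 65.8, 0.21, 0.01),
        ("SJ", 17, 62.3, 0.24, 0.01),
        ("TA", 11, 56.4, 0.18, 0.01),
    ],
    columns=["pop", "n", "PPL", "HE", "SE_HE"],
)

#: SGS table. sigma_g entries are None where the slope was not significant.
SGS = pd.DataFrame(
    [
        ("LA", 0.02, 0.04, -0.01, True, 64.3, 0.69, 273.1, 386.3, 546.3, 863.7),
        ("MI", 0.01, 0.01, -0.01, False, None, 22.05, None, None, None, None),
        ("RO", 0.05, 0.05, -0.05, True, 20.5, 8.19, 44.6, 63.1, 89.2, 141.1),
        ("TA", 0.02, 0.00, -0.02, False, None, 50.00, None, None, None, None),
        ("SJ", 0.01, 0.00, -0.01, False, None, 12.62, None, None, None, None),
        ("QU", 0.07, 0.15, -0.06, True, 15.2, 2.72, 66.7, 94.3, 133.3, 210.8),
        ("QUA", 0.03, 0.06, -0.03, True, 31.9, 3.40, 86.4, 122.1, 172.7, 273.1),
        ("QUB", 0.23, 0.14, -0.20, True, 4.4, 2.03, 41.4, 58.5, 82.8, 130.9),
    ],
    columns=[
        "pop", "Sp", "F1", "bF", "significant", "Nb", "DE_per_ha",
        "sigma_g", "sigma_g_half", "sigma_g_quarter", "sigma_g_tenth",
    ],
)

#: AMOVA partition of the same survey (band-phenotype distances).
AMOVA = {
    "df_between": 5,
    "df_within": 164,
    "ss_between": 3683.96,
    "ss_within": 6623.03,
    "pct_between": 39.3,
    "pct_within": 60.7,
    "phi_st": 0.393,
    "p": 0.001,
}

#: Non-hierarchical Wright F_ST and its G-test p (5000 permutations).
FST = {"fst": 0.42, "p": 5e-4}

#: Number of neutral dominant loci behind every printed statistic.
N_LOCI = 401
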