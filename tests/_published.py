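"""Frozen reference values for the 17-site district study.

HQ values (2 decimals) per site for children/teenagers/adults, and total
daily intake (3 decimals, mg/day) per site as (min, max, avg) triples per
cohort. These are the independently tabulated values the deterministic
engine must reproduce.
"""

# site -> (children, teenagers, adults) mean-concentration HQ, 2 decimals
HQ_TABLE = {
    "S1": (0.50, 0.39, 0.31),
    "S2": (1.21, 0.93, 0.75),
    "S3": (1.56, 1.20, 0.96),
    "S4": (1.56, 1.20, 0.96),
    "S5": (1.56, 1.20, 0.96),
    "S6": (2.08, 1.60, 1.28),
    "S7": (1.56, 1.20, 0.96),
    "S8": (2.25, 1.73, 1.39),
    "S9": (2.17, 1.67, 1.34),
    "S10": (2.41, 1.85, 1.49),
    "S11": (2.17, 1.67, 1.34),
    "S12": (1.94, 1.49, 1.20),
    "S13": (2.95, 2.27, 1.82),
    "S14": (2.10, 1.61, 1.29),
    "S15": (3.29, 2.53, 2.03),
    "S16": (2.30, 1.77, 1.42),
    "S17": (2.31, 1.77, 1.42),
}

# site -> ((ch_min, ch_max, ch_avg), (te_min, te_max, te_avg),
#          (ad_min, ad_max, ad_avg)) total daily intake, mg/day, 3 decimals
TDI_TABLE = {
    "S1": ((0.390, 0.546, 0.452), (1.000, 1.400, 1.160), (1.250, 1.750, 1.450)),
    "S2": ((1.030, 1.154, 1.092), (2.640, 2.960, 2.800), (3.300, 3.700, 3.500)),
    "S3": ((1.342, 1.482, 1.404), (3.440, 3.800, 3.600), (4.300, 4.750, 4.500)),
    "S4": ((1.287, 1.482, 1.404), (3.300, 3.800, 3.600), (4.125, 4.750, 4.500)),
    "S5": ((1.326, 1.466, 1.404), (3.400, 3.760, 3.600), (4.250, 4.700, 4.500)),
    "S6": ((1.466, 2.184, 1.872), (3.760, 5.600, 4.800), (4.700, 7.000, 6.000)),
    "S7": ((1.287, 1.482, 1.404), (3.300, 3.800, 3.600), (4.125, 4.750, 4.500)),
    "S8": ((1.872, 2.262, 2.028), (4.800, 5.800, 5.200), (6.000, 7.250, 6.500)),
    "S9": ((1.404, 2.418, 1.950), (3.600, 6.200, 5.000), (4.500, 7.750, 6.250)),
    "S10": ((1.794, 2.418, 2.168), (4.600, 6.200, 5.560), (5.750, 7.750, 6.950)),
    "S11": ((1.794, 2.184, 1.950), (4.600, 5.600, 5.000), (5.750, 7.000, 6.250)),
    "S12": ((0.858, 2.184, 1.747), (2.200, 5.600, 4.480), (2.750, 7.000, 5.600)),
    "S13": ((2.262, 3.042, 2.652), (5.800, 7.800, 6.800), (7.250, 9.750, 8.500)),
    "S14": ((1.248, 2.340, 1.888), (3.200, 6.000, 4.840), (4.000, 7.500, 6.050)),
    "S15": ((2.808, 3.120, 2.964), (7.200, 8.000, 7.600), (9.000, 10.000, 9.500)),
    "S16": ((1.716, 2.418, 2.067), (4.400, 6.200, 5.300), (5.500, 7.750, 6.625)),
    "S17": ((1.950, 2.184, 2.075), (5.000, 5.600, 5.320), (6.250, 7.000, 6.650)),
}

COHORT_ORDER = ("children", "teenagers", "adults")

# district-level reference numbers
DISTRICT_MEAN_2DP = 2.30
EXCEEDANCE_PCT_1DP = 88.2
N_EXCEEDING = 15

# headline hazard quotients
HQ_MAX_CHILDREN = 3.29   # Durga Colony (S15)
HQ_MIN_ADULTS = 0.31     # Nadrai Gate (S1)
HQ_MAX_TEENAGERS = 2.53

# cohort means of the mean-concentration HQ
MEAN_HQ = {"children": 1.99, "teenagers": 1.53, "adults": 1.23}

# dental-endpoint prevalence, % of sites with HQ > 1 (display-rounded)
DENTAL_PREVALENCE = {"children": 94, "teenagers": 88, "adults": 65}

# intake ranges (avg-variant TDI, mg/day, 2-decimal endpoints)
TDI_AVG_RANGE = {
    "children": (0.45, 2.96),
    "teenagers": (1.16, 7.60),
    "adults": (1.45, 9.50),
}

# surrogate accuracy floors (coefficient of determination)
ANN_TRAIN_R2 = 0.9989
ANN_TEST_R2 = 0.9870
ANN_TRAIN_RMSE = 0.02230
ANN_TEST_RMSE = 0.0267
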