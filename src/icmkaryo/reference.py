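"""Published reference values for the maize (Zea mays, 2n = 2x = 20) karyotype.

These tables transcribe the published per-arm 2C DNA amounts of the ten
maize chromosome pairs measured by Feulgen image cytometry anchored on a
flow-cytometric nuclear 2C value, together with the external chromosome-level
values (flow karyotyping, an earlier ICM study on 'Black Mexican Sweet Corn',
and the B73 reference-genome assembly) used for cross-study comparison.

They serve two purposes: as the DNA composition of the default synthetic
karyotype, and as fixed inputs for reproducing the published summary numbers
(peak-ratio sizing, pg->bp conversion, percent differences).
"""

from __future__ import annotations

# -- Flow cytometry (nuclear sizing) -----------------------------------------

#: 2C of the internal standard line 'CE-777', pg.
STANDARD_2C_PG = 5.57
#: G0/G1 peak channel of the internal standard in the representative histogram.
STANDARD_PEAK_CHANNEL = 200.0
#: G0/G1 peak channel of the sample line 'AL Bandeirante'.
SAMPLE_PEAK_CHANNEL = 219.0
#: Published mean nuclear 2C of 'AL Bandeirante' (pg) and its replicate SD.
NUCLEAR_2C_PG = 6.10
NUCLEAR_2C_SD_PG = 0.044
#: Accepted G0/G1 peak CV range (%) in the published measurements.
CV_RANGE_PCT = (3.00, 4.10)
#: Representative per-peak CVs (%): standard, sample.
CV_STANDARD_PCT = 3.20
CV_SAMPLE_PCT = 3.80

# -- Chromosomal 2C DNA per arm/satellite, pg (mean, sd) ----------------------
# Keys: pair number -> {portion -> (2C pg, sd pg)}; portions: SAT, S, L.

TABLE_2C_ARM_PG: dict[int, dict[str, tuple[float, float]]] = {
    1: {"S": (0.376, 0.027), "L": (0.427, 0.017)},
    2: {"S": (0.269, 0.023), "L": (0.456, 0.030)},
    3: {"S": (0.237, 0.024), "L": (0.440, 0.040)},
    4: {"S": (0.239, 0.031), "L": (0.395, 0.040)},
    5: {"S": (0.271, 0.019), "L": (0.355, 0.020)},
    6: {"SAT": (0.053, 0.009), "S": (0.171, 0.021), "L": (0.366, 0.035)},
    7: {"S": (0.156, 0.023), "L": (0.408, 0.026)},
    8: {"S": (0.131, 0.013), "L": (0.402, 0.030)},
    9: {"S": (0.215, 0.025), "L": (0.346, 0.028)},
    10: {"S": (0.131, 0.008), "L": (0.255, 0.013)},
}

#: Published 1C values per arm/satellite, bp x 1e9 (rounded to 3 decimals).
TABLE_1C_ARM_BP_E9: dict[int, dict[str, float]] = {
    1: {"S": 0.184, "L": 0.209},
    2: {"S": 0.132, "L": 0.223},
    3: {"S": 0.116, "L": 0.215},
    4: {"S": 0.117, "L": 0.193},
    5: {"S": 0.133, "L": 0.174},
    6: {"SAT": 0.026, "S": 0.084, "L": 0.179},
    7: {"S": 0.076, "L": 0.200},
    8: {"S": 0.064, "L": 0.197},
    9: {"S": 0.105, "L": 0.169},
    10: {"S": 0.064, "L": 0.125},
}

# -- Chromosome-level morphometric anchors ------------------------------------

#: Published mean chromosome areas, um^2 (chromosome -> area); only the four
#: printed anchors; remaining areas scale linearly with pair DNA.
MEAN_AREA_UM2 = {1: 9.478, 8: 6.342, 9: 6.672, 10: 4.652}
#: Published per-chromosome IOD extremes (area x OD).
MEAN_IOD = {1: 10.679, 8: 7.083, 9: 7.454, 10: 5.196}
#: Published mean OD extremes.
MEAN_OD = {1: 1.127, 5: 1.112, 10: 1.117}

# -- pg <-> bp conversion ------------------------------------------------------

#: Base pairs per picogram of DNA.
BP_PER_PG = 0.978e9

# -- External chromosome-level 1C values (bp) for cross-study comparison ------

#: Flow karyotyping (Lee et al.), chromosome 1.
FLOW_KARYOTYPE_1C_BP = {1: 0.365e9}
#: B73 reference-genome assembly sizes (chromosomes 1 and 10 as printed).
SEQUENCING_1C_BP = {1: 0.301e9, 10: 0.150e9}
#: Earlier ICM study on 'Black Mexican Sweet Corn', chromosome 10.
BMSC_ICM_1C_BP = {10: 0.234e9}

# -- Instrument-qualification anchors -----------------------------------------

LINEARITY_R2_MIN = 0.999
UNIFORMITY_CV_MAX_PCT = 3.0
STABILIZATION_TIME_MIN = 12.0


def pair_total_2c_pg(pair_id: int) -> float:
    """Sum the published arm/satellite 2C values of one pair (pg)."""
    return sum(v[0] for v in TABLE_2C_ARM_PG[pair_id].values())


def complement_total_2c_pg() -> float:
    """Sum of all per-arm 2C values over the ten pairs (pg); ~6.10."""
    return sum(pair_total_2c_pg(p) for p in TABLE_2C_ARM_PG)
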