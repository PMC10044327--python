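"""Frozen per-axis %RMSE cells and printed "Average +- SE" summaries from the
published evaluation whose aggregation arithmetic this package mirrors.

Each row: (per-axis triple, printed mean string, printed SE string). Printed
strings retain the original precision so tests can compare at half the last
printed digit.
"""

# Posture-control motion, rows keyed by input pattern id.
PCM_TABLE = {
    1: {"grf": ((11.2, 11.3, 7.33), "9.94", "1.31"),
        "grm": ((13.2, 16.3, 11.3), "13.6", "1.46")},
    2: {"grf": ((7.83, 9.00, 6.67), "7.83", "0.67"),
        "grm": ((9.50, 7.33, 9.83), "8.89", "0.78")},
    3: {"grf": ((7.67, 9.17, 6.83), "7.89", "0.68"),
        "grm": ((7.83, 7.17, 9.33), "8.11", "0.64")},
    4: {"grf": ((11.0, 11.8, 7.33), "10.04", "1.38"),
        "grm": ((13.5, 18.2, 11.3), "14.33", "2.03")},
    5: {"grf": ((8.17, 11.3, 6.67), "8.71", "1.36"),
        "grm": ((16.8, 7.83, 10.0), "11.54", "2.70")},
    6: {"grf": ((8.00, 10.0, 6.67), "8.22", "0.97"),
        "grm": ((10.7, 7.67, 9.67), "9.35", "0.89")},
}

# Stepping motion.
SM_TABLE = {
    1: {"grf": ((11.0, 11.5, 16.5), "13", "1.76"),
        "grm": ((12.8, 14.7, 10.3), "12.6", "1.27")},
    2: {"grf": ((7.3, 11.3, 15.7), "11.43", "2.43"),
        "grm": ((12.0, 8.83, 9.33), "10.05", "1.20")},
    3: {"grf": ((7.17, 9.17, 15.2), "10.51", "2.41"),
        "grm": ((11.0, 8.83, 8.83), "9.55", "0.72")},
    4: {"grf": ((11.0, 11.7, 17.0), "13.23", "1.89"),
        "grm": ((13.3, 15.0, 10.3), "12.87", "1.37")},
    5: {"grf": ((8.50, 11.3, 16.0), "11.93", "2.19"),
        "grm": ((16.0, 10.3, 10.0), "12.1", "1.95")},
    6: {"grf": ((8.00, 10.2, 15.3), "11.17", "2.16"),
        "grm": ((12.3, 10.2, 9.50), "10.67", "1.05")},
}

# SM GRM SE cells of rows 2 and 6 are arithmetic slips in the source table:
# they equal the n-1 SD over all six axis values of the row / sqrt(6) instead
# of the three-axis convention every other cell follows.
ANOMALOUS_SE_CELLS = (("sm", 2, "grm"), ("sm", 6, "grm"))


def printed_tolerance(printed: str) -> float:
    """Half the last printed digit (e.g. '9.94' -> 0.005, '13' -> 0.5)."""
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return 0.5 * 10.0 ** (-decimals) + 1e-12
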