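"""Published provincial summary tables used as inputs for consistency checks.

These are the printed, 3-decimal (or significance-starred) result tables of the
Gansu TCM-hospital study whose raw city-level panel was never deposited.  Tests
treat them as data: recomputing one column from another checks the package's
arithmetic conventions (decompositions, geometric-mean averaging, equity
ratios) against what the published tables actually satisfy.
"""

# 2024 cross-section, stage 1 (raw data): dmu -> (TE, PTE, SE, scale_returns, label)
STAGE1_EFFICIENCY = {
    "LZ": (1.000, 1.000, 1.000, "-", "efficient"),
    "JYG": (1.000, 1.000, 1.000, "-", "efficient"),
    "JC": (1.000, 1.000, 1.000, "-", "efficient"),
    "BY": (0.962, 0.975, 0.987, "irs", "ineffective"),
    "TS": (1.000, 1.000, 1.000, "-", "efficient"),
    "WW": (1.000, 1.000, 1.000, "-", "efficient"),
    "ZY": (0.975, 1.000, 0.975, "drs", "weakly-effective"),
    "PL": (0.908, 0.919, 0.988, "irs", "ineffective"),
    "JQ": (1.000, 1.000, 1.000, "-", "efficient"),
    "QY": (1.000, 1.000, 1.000, "-", "efficient"),
    "DX": (1.000, 1.000, 1.000, "-", "efficient"),
    "LN": (1.000, 1.000, 1.000, "-", "efficient"),
    "LX": (1.000, 1.000, 1.000, "-", "efficient"),
    "GN": (0.610, 0.695, 0.878, "irs", "ineffective"),
}
STAGE1_COLUMN_MEANS = (0.961, 0.971, 0.988)

# 2024 cross-section, stage 3 (environment-adjusted inputs)
STAGE3_EFFICIENCY = {
    "LZ": (1.000, 1.000, 1.000), "JYG": (1.000, 1.000, 1.000),
    "JC": (0.988, 1.000, 0.988), "BY": (0.956, 0.997, 0.959),
    "TS": (1.000, 1.000, 1.000), "WW": (1.000, 1.000, 1.000),
    "ZY": (1.000, 1.000, 1.000), "PL": (0.911, 0.925, 0.984),
    "JQ": (1.000, 1.000, 1.000), "QY": (1.000, 1.000, 1.000),
    "DX": (1.000, 1.000, 1.000), "LN": (1.000, 1.000, 1.000),
    "LX": (1.000, 1.000, 1.000), "GN": (0.619, 0.767, 0.807),
}
STAGE3_COLUMN_MEANS = (0.962, 0.978, 0.981)

# Malmquist by period pair: pair -> (EC, TC, PECT, SEC, TFP)
MALMQUIST_BY_PERIOD = {
    "2018-2019": (0.969, 0.967, 1.000, 0.969, 0.937),
    "2019-2020": (1.016, 0.813, 0.998, 1.019, 0.827),
    "2020-2021": (0.984, 0.984, 0.988, 0.995, 0.968),
    "2021-2022": (0.985, 0.823, 1.011, 0.974, 0.811),
    "2022-2023": (1.001, 1.318, 0.982, 1.020, 1.319),
    "2023-2024": (1.016, 0.931, 1.003, 1.013, 0.946),
}
MALMQUIST_BY_DMU_TFP = {
    "LZ": 1.001, "JYG": 0.998, "JC": 0.950, "BY": 0.906, "TS": 0.946,
    "WW": 0.989, "ZY": 0.970, "PL": 0.951, "JQ": 0.960, "QY": 0.988,
    "DX": 0.960, "LN": 0.929, "LX": 0.961, "GN": 0.870,
}
MALMQUIST_AVERAGE_TFP = 0.955  # printed grand average of both tables

# 2024 concentration: dmu -> {indicator: (HRAD, ratio)} plus PAD
CONCENTRATION_2024 = {
    "LZ": {"staff": (4.995, 0.766), "devices": (3.477, 0.533),
           "institutions": (3.631, 0.557), "beds": (3.866, 0.593), "PAD": 6.522},
    "JYG": {"staff": (0.192, 0.039), "devices": (0.078, 0.016),
            "institutions": (0.132, 0.027), "beds": (0.178, 0.036), "PAD": 4.957},
    "JC": {"staff": (0.955, 1.105), "devices": (0.566, 0.655),
           "institutions": (1.118, 1.295), "beds": (0.524, 0.607), "PAD": 0.864},
    "BY": {"staff": (1.241, 0.875), "devices": (0.758, 0.534),
           "institutions": (1.392, 0.982), "beds": (0.907, 0.640), "PAD": 1.418},
    "TS": {"staff": (3.537, 0.908), "devices": (2.491, 0.640),
           "institutions": (4.758, 1.222), "beds": (3.868, 0.993), "PAD": 3.894},
    "WW": {"staff": (0.926, 1.092), "devices": (3.052, 3.599),
           "institutions": (0.920, 1.085), "beds": (1.096, 1.292), "PAD": 0.848},
    "ZY": {"staff": (0.719, 1.310), "devices": (0.421, 0.767),
           "institutions": (0.750, 1.366), "beds": (0.613, 1.117), "PAD": 0.549},
    "PL": {"staff": (3.789, 1.221), "devices": (2.921, 0.941),
           "institutions": (4.373, 1.409), "beds": (3.722, 1.199), "PAD": 3.103},
    "JQ": {"staff": (0.128, 1.223), "devices": (0.148, 1.414),
           "institutions": (0.131, 1.257), "beds": (0.106, 1.014), "PAD": 0.104},
    "QY": {"staff": (1.423, 0.943), "devices": (1.123, 0.744),
           "institutions": (2.396, 1.587), "beds": (1.372, 0.909), "PAD": 1.509},
    "DX": {"staff": (2.419, 0.995), "devices": (1.865, 0.767),
           "institutions": (2.053, 0.845), "beds": (3.363, 1.384), "PAD": 2.431},
    "LN": {"staff": (1.414, 0.876), "devices": (0.514, 0.319),
           "institutions": (0.669, 0.414), "beds": (1.597, 0.990), "PAD": 1.614},
    "LX": {"staff": (3.010, 0.608), "devices": (8.898, 1.798),
           "institutions": (2.150, 0.435), "beds": (5.223, 1.056), "PAD": 4.949},
    "GN": {"staff": (0.396, 1.391), "devices": (0.625, 2.194),
           "institutions": (0.413, 1.451), "beds": (0.267, 0.937), "PAD": 0.285},
}
HRAD_RANGE_2024 = (0.078, 8.898)

# province-vs-nation by year: year -> {indicator: (HRAD, ratio)} plus PAD
CONCENTRATION_BY_YEAR = {
    2018: {"staff": (0.612, 0.588), "devices": (0.309, 0.298),
           "institutions": (0.781, 0.751), "beds": (0.686, 0.659), "PAD": 1.040},
    2019: {"staff": (0.620, 0.578), "devices": (0.479, 0.447),
           "institutions": (0.636, 0.593), "beds": (0.773, 0.720), "PAD": 1.073},
    2020: {"staff": (0.669, 0.657), "devices": (0.482, 0.474),
           "institutions": (0.650, 0.638), "beds": (0.800, 0.786), "PAD": 1.018},
    2021: {"staff": (0.713, 0.704), "devices": (0.584, 0.577),
           "institutions": (0.676, 0.667), "beds": (0.829, 0.818), "PAD": 1.013},
    2022: {"staff": (0.733, 0.718), "devices": (0.715, 0.700),
           "institutions": (0.696, 0.682), "beds": (0.842, 0.825), "PAD": 1.021},
    2023: {"staff": (0.823, 0.821), "devices": (0.769, 0.767),
           "institutions": (0.666, 0.664), "beds": (0.951, 0.948), "PAD": 1.003},
}
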