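"""Default indicator roles and published scale targets for the synthetic generator.

The targets are the descriptive statistics (n = 98 city-year observations,
14 cities x 7 years) of the Gansu provincial TCM-hospital statistical bulletins:
mean, sample sd, max and min per indicator.  The generator matches the mean/sd
magnitudes; max/min are used only for feasibility checks, since extreme order
statistics of a 98-cell draw are not a sensible calibration target.

City land areas are not published in the bulletins' summary table; the area
targets below are package choices resembling the real spread of Gansu's
prefectures (a few thousand to ~2e5 km^2).
"""

# name -> (role, units, mean, sd, max, min)
DEFAULT_INDICATOR_TARGETS = {
    "tcm_staff": ("input", "persons", 1_468.980, 876.752, 5_052.0, 195.0),
    "tcm_devices": ("input", "devices > 5,000 CNY", 474.878, 397.170, 2_233.0, 8.0),
    "tcm_institutions": ("input", "institutions", 127.786, 80.446, 555.0, 3.0),
    "tcm_beds": ("input", "beds", 3_333.418, 1_972.546, 7_768.0, 482.0),
    "tcm_prescriptions": ("output", "prescriptions", 1_795_891.500, 1_078_139.922,
                          6_056_365.0, 87_506.0),
    "tcm_consultations": ("output", "1e4 visits", 161.184, 90.573, 470.550, 27.400),
    "tcm_discharges": ("output", "persons", 88_402.000, 57_473.290, 249_708.0, 9_836.0),
    "gdp_per_capita": ("environment", "CNY", 48_092.415, 31_379.621, 143_784.0, 12_447.0),
    "resident_population": ("environment", "1e4 persons", 180.530, 105.382, 443.650, 25.200),
    "tcm_outpatient_share": ("environment", "percent", 11.996, 9.769, 28.710, 0.210),
    "land_area": ("area", "km^2", 30_414.0, 40_000.0, 200_000.0, 2_900.0),
}

DEFAULT_DMUS = ["LZ", "JYG", "JC", "BY", "TS", "WW", "ZY",
                "PL", "JQ", "QY", "DX", "LN", "LX", "GN"]

DEFAULT_PERIODS = [str(y) for y in range(2018, 2025)]
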