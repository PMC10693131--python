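"""Canonical column names of the weekly national feature table.

The table has 18 environmental inputs (6 air pollutants, 8 weather
variables, 3 pollen hazard indices, influenza counts), 4 confounders
(week-of-year, epoch date, holidays-per-week, MERS counts) and 2 targets
(weekly outpatient and ER asthma counts).
"""

POLLUTANTS = ["co", "no2", "o3", "pm10", "pm25", "so2"]

WEATHER = [
    "temp_mean",
    "temp_min",
    "temp_max",
    "diurnal_temp_range",
    "humidity",
    "precipitation",
    "solar_radiation",
    "wind_speed",
]

#: variables measured daily at monitoring stations
STATION_VARIABLES = POLLUTANTS + WEATHER

POLLEN = ["oak_pollen", "pine_pollen", "grass_pollen"]

ENVIRONMENT_COLUMNS = POLLUTANTS + WEATHER + POLLEN + ["influenza"]

CONFOUNDER_COLUMNS = ["week_of_year", "date", "holidays_per_week", "mers"]

#: the 22 model inputs, in canonical order
INPUT_COLUMNS = ENVIRONMENT_COLUMNS + CONFOUNDER_COLUMNS

TARGET_COLUMNS = ["outpatient", "er"]

assert len(ENVIRONMENT_COLUMNS) == 18
assert len(INPUT_COLUMNS) == 22
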