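{
  "_source": "US-EPA Technical Assistance Document for the Reporting of Daily Air Quality (AQI), airnow.gov; concentration units: O3 8-hour ppm, CO 8-hour ppm, SO2 1-hour ppb, NO2 1-hour ppb",
  "O3": {
    "units": "ppm",
    "truncation_decimals": 3,
    "rows": [
      [0.0, 0.054, 0, 50],
      [0.055, 0.07, 51, 100],
      [0.071, 0.085, 101, 150],
      [0.086, 0.105, 151, 200],
      [0.106, 0.2, 201, 300]
    ]
  },
  "CO": {
    "units": "ppm",
    "truncation_decimals": 1,
    "rows": [
      [0.0, 4.4, 0, 50],
      [4.5, 9.4, 51, 100],
      [9.5, 12.4, 101, 150],
      [12.5, 15.4, 151, 200],
      [15.5, 30.4, 201, 300],
      [30.5, 40.4, 301, 400],
      [40.5, 50.4, 401, 500]
    ]
  },
  "SO2": {
    "units": "ppb",
    "truncation_decimals": 0,
    "rows": [
      [0, 35, 0, 50],
      [36, 75, 51, 100],
      [76, 185, 101, 150],
      [186, 304, 151, 200],
      [305, 604, 201, 300],
      [605, 804, 301, 400],
      [805, 1004, 401, 500]
    ]
  },
  "NO2": {
    "units": "ppb",
    "truncation_decimals": 0,
    "rows": [
      [0, 53, 0, 50],
      [54, 100, 51, 100],
      [101, 360, 101, 150],
      [361, 649, 151, 200],
      [650, 1249, 201, 300],
      [1250, 1649, 301, 400],
      [1650, 2049, 401, 500]
    ]
  }
}
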