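region,year,total,male,female
All,111,79.84,76.63,83.28
New Taipei,111,81.32,78.26,84.39
Taipei,111,83.75,80.55,86.94
Taoyuan,111,81.04,77.93,84.14
Taichung,111,80.37,77.34,83.35
Tainan,111,79.67,76.72,82.57
Kaohsiung,111,79.47,76.56,82.43
Keelung,111,78.40,74.83,81.96
Hsinchu City,111,81.96,78.83,85.08
Hsinchu County,111,80.50,77.65,83.36
Miaoli,111,78.89,75.66,82.12
Changhua,111,78.70,75.48,81.89
Nantou,111,78.57,75.50,81.61
Yunlin,111,77.66,74.39,80.93
Chiayi City,111,78.56,75.59,81.56
Chiayi County,111,77.53,74.02,80.95
Pingtung,111,78.50,75.43,81.60
Yilan,111,78.07,74.65,81.43
Hualien,111,75.45,71.84,79.07
Taitung,111,74.08,70.04,78.17
Penghu,111,78.70,75.27,82.23
Kinmen,111,81.72,78.36,85.30
Lienchiang,111,80.99,77.47,84.10
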