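study,subject_id,body_mass_g,rco2_ic_L_per_day,eq1_L_per_day,eq1_pct,eq6_L_per_day,eq6_pct,eq7_L_per_day,eq7_pct,coward1985_L_per_day,coward1985_pct,speakman717_L_per_day,speakman717_pct,eq10_L_per_day,eq10_pct
Roberts et al.,D3,1090.00,12.50,9.09,-27.27,11.4,-8.5,9.94,-20.49,,,12.80,2.40,12.85,2.81
Westerterp et al.,B3,1115.00,11.37,10.00,-12.08,11.4,0.3,10.51,-7.63,8.53,-25.04,12.44,9.36,12.22,7.44
Westerterp et al.,B7,1195.00,14.58,13.60,-6.74,15.3,4.8,14.20,-2.57,11.91,-18.32,16.60,13.85,16.16,10.82
Roberts et al.,D2,1378.00,13.70,13.64,-0.45,15.9,15.8,14.44,5.40,,,17.39,26.93,16.72,22.07
Jensen et al.,A10,1414.85,17.72,13.48,-23.91,15.8,-10.8,14.32,-19.18,14.59,-17.65,17.37,-1.98,16.65,-6.02
Roberts et al.,D4,1496.00,17.00,14.99,-11.85,17.8,4.7,16.00,-5.87,,,19.63,15.47,18.68,9.87
Jensen et al.,A1,1520.65,18.29,13.13,-28.24,15.4,-15.7,13.95,-23.71,12.90,-29.50,16.96,-7.29,16.10,-11.97
Westerterp et al.,B1,1545.00,14.83,13.94,-6.03,16.2,9.2,14.75,-0.55,9.86,-33.50,17.74,19.63,16.82,13.40
Jensen et al.,A5,1596.45,19.74,19.16,-2.95,21.6,9.6,20.05,1.58,17.70,-10.36,23.53,19.22,22.25,12.73
Westerterp et al.,B4,1600.00,15.52,14.61,-5.85,17.2,11.0,15.55,0.21,11.80,-24.00,18.94,22.07,17.86,15.08
Westerterp et al.,B6,1640.00,18.70,17.48,-6.53,19.8,5.9,18.31,-2.04,15.12,-19.15,21.56,15.31,20.32,8.69
Westerterp et al.,B2,1660.00,17.76,16.77,-5.58,19.5,9.7,17.75,-0.08,13.71,-22.79,21.35,20.21,20.05,12.88
Jensen et al.,A8,1692.15,20.01,18.01,-10.00,20.9,4.2,19.04,-4.87,18.38,-8.15,22.85,14.15,21.41,6.96
Jensen et al.,A7,1702.70,22.88,26.77,16.98,29.3,28.0,27.68,20.96,26.82,17.18,31.58,37.99,29.76,30.06
Jensen et al.,A9,1709.20,21.17,13.92,-34.24,16.5,-21.9,14.87,-29.79,15.35,-27.49,18.23,-13.89,17.01,-19.65
Jensen et al.,A11,1783.30,22.61,18.81,-16.79,21.6,-4.4,19.83,-12.31,19.35,-14.44,23.63,4.50,22.01,-2.64
Jensen et al.,A12,1824.10,21.17,18.87,-10.85,21.4,1.2,19.79,-6.50,19.78,-6.55,23.33,10.25,21.72,2.64
Westerterp et al.,B8,1830.00,21.23,19.09,-10.09,21.8,2.6,20.06,-5.52,18.06,-14.93,23.75,11.89,22.09,4.04
Westerterp et al.,B5,1860.00,18.97,15.54,-18.08,18.4,-3.2,16.56,-12.70,14.00,-26.19,20.22,6.60,18.65,-1.71
Jensen et al.,A6,1862.40,18.44,14.19,-23.06,16.8,-9.0,15.12,-17.99,14.76,-19.98,18.48,0.21,17.03,-7.63
Jensen et al.,A4,1880.70,25.36,22.30,-12.06,25.1,-0.9,23.32,-8.03,22.64,-10.74,27.32,7.74,25.39,0.10
Jensen et al.,A3,1894.95,25.47,12.37,-51.44,16.4,-35.7,13.81,-45.77,15.32,-39.84,18.53,-27.24,16.69,-34.47
Jones et al.,C6,1920.00,21.95,21.99,0.16,25.7,17.3,23.34,6.33,,,28.27,28.77,25.99,18.40
Jensen et al.,A2,1996.80,23.04,19.40,-15.79,22.5,-2.5,20.50,-10.98,19.33,-16.09,24.60,6.81,22.56,-2.08
Jones et al.,C1,2570.00,27.55,25.42,-7.75,30.7,11.4,27.32,-0.85,,,33.97,23.30,29.56,7.28
Roberts et al.,D1,2575.00,27.90,21.67,-22.33,25.7,-7.9,23.12,-17.14,,,28.31,1.45,24.82,-11.04
Jones et al.,C4,2590.00,25.98,22.39,-13.83,25.7,-1.1,23.58,-9.24,,,28.08,8.05,24.97,-3.92
Jones et al.,C5,2790.00,28.00,27.36,-2.28,31.9,13.8,28.98,3.50,,,34.93,24.75,30.55,9.11
Jones et al.,C8,2980.00,32.70,27.02,-17.37,32.0,-2.3,28.80,-11.94,,,35.19,7.59,30.23,-7.55
Jones et al.,C9,3390.00,33.82,33.14,-2.02,38.3,13.3,35.01,3.51,,,41.96,24.05,35.96,6.31
Jones et al.,C3,3440.00,34.27,32.11,-6.32,36.9,7.6,33.83,-1.30,,,40.29,17.55,34.64,1.08
Jones et al.,C2,3890.00,41.22,42.11,2.16,47.7,15.9,44.14,7.09,,,51.99,26.13,44.58,8.17
Jones et al.,C7,4030.00,37.18,34.56,-7.04,41.5,11.7,37.08,-0.28,,,45.93,23.53,37.46,0.73
Jones et al.,C2b,4160.00,50.40,46.29,-8.16,51.9,2.9,48.30,-4.17,,,56.27,11.65,48.48,-3.81
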