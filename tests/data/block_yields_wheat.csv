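block,actual,weight_based,percentile_based,rf,xgb,gru,lstm,gru_kriging,lstm_kriging
Adampur,50.08,43.71,47.07,48.80,45.74,45.46,43.37,49.12,49.28
Agroha,52.41,48.94,52.70,51.22,48.35,48.00,45.76,48.72,48.96
Barwala,51.51,50.05,53.90,51.72,47.43,49.97,47.02,50.53,50.24
Hansi1,51.19,48.13,51.83,50.29,46.31,49.73,47.05,51.08,51.41
Hansi2,46.64,43.55,46.90,46.22,44.25,46.23,44.36,46.63,47.06
Hisar1,47.94,47.57,51.22,46.67,45.33,48.87,45.97,50.94,50.85
Hisar2,49.05,47.90,51.58,49.10,46.43,47.03,44.52,50.23,49.98
Narnaund,49.05,48.24,51.94,49.78,46.01,49.29,46.57,49.43,49.41
Uklana,53.71,49.62,53.44,52.49,48.80,51.03,47.66,51.82,51.02
Bawani Khera,44.60,38.62,42.95,41.73,41.43,48.37,45.88,44.30,45.30
Behal,42.69,38.99,43.36,36.92,37.66,44.96,42.35,40.88,43.58
Bhiwani,39.03,37.78,42.02,35.89,37.39,44.65,42.25,40.57,37.05
Kairu,39.86,39.45,43.88,34.92,36.82,45.19,42.80,41.12,38.42
Loharu,43.40,39.94,44.42,37.28,37.89,45.09,42.66,41.01,43.20
Siwani,42.05,37.44,41.64,37.64,38.10,43.69,40.13,39.61,40.37
Tosham,38.04,38.68,43.02,34.56,36.11,45.10,42.49,41.02,41.26
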