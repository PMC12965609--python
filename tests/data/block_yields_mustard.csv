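block,actual,weight_based,percentile_based,rf,xgb,gru,lstm,gru_kriging,lstm_kriging
Adampur,17.38,15.53,24.52,16.11,17.59,17.60,15.44,17.70,17.63
Agroha,21.31,17.19,27.15,18.98,20.42,19.18,16.86,18.48,18.64
Barwala,18.86,17.27,27.28,18.14,19.44,19.31,16.94,18.77,19.31
Hansi1,17.78,16.70,26.38,16.86,17.79,19.45,16.58,19.06,18.64
Hansi2,21.96,15.60,24.64,19.72,20.11,16.94,14.75,19.49,19.68
Hisar1,18.93,16.23,25.63,17.29,18.66,18.56,15.58,19.57,19.51
Hisar2,17.93,16.45,25.98,16.22,18.15,17.85,15.60,18.74,18.93
Narnaund,21.26,17.09,26.99,20.72,20.54,19.74,17.11,21.03,21.09
Uklana,21.98,17.87,28.23,20.49,20.87,21.28,17.99,21.14,20.24
Bawani Khera,11.31,13.67,22.29,13.11,13.65,16.98,15.28,14.98,17.69
Behal,12.81,13.39,21.84,13.74,14.33,15.14,13.26,13.14,11.47
Bhiwani,15.33,12.82,20.91,14.51,15.32,14.40,12.68,12.40,13.78
Kairu,14.23,13.30,21.68,16.01,15.49,15.30,13.40,13.30,13.15
Loharu,15.28,13.42,21.87,16.64,16.03,15.68,13.58,13.68,13.66
Siwani,10.05,12.14,19.80,12.38,13.41,14.73,12.19,12.72,11.33
Tosham,11.63,12.48,20.35,13.13,13.35,15.05,12.82,13.05,13.63
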