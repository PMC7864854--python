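country,cfr_high,cfr_medium,cfr_low,cfr_total,delta_high_medium,delta_medium_low,delta_high_low
Austria,1.38,1.62,1.98,1.61,-0.19,-0.33,-0.52
Belarus,1.43,1.76,1.96,1.68,-0.29,-0.14,-0.44
Belgium,1.74,1.65,1.78,1.72,0.10,-0.11,-0.01
Finland,1.81,1.99,1.97,1.90,-0.15,-0.01,-0.16
France,1.76,1.87,2.10,1.87,-0.09,-0.22,-0.31
Germany,1.40,1.51,1.67,1.50,-0.11,-0.16,-0.27
Greece,1.54,1.69,2.09,1.76,-0.14,-0.33,-0.48
Hungary,1.66,1.77,2.42,1.86,-0.10,-0.59,-0.69
Ireland,1.88,2.10,2.38,2.09,-0.22,-0.28,-0.50
Lithuania,1.56,1.90,2.06,1.80,-0.29,-0.14,-0.43
Netherlands,1.71,1.82,1.89,1.81,-0.10,-0.03,-0.12
Norway,1.99,2.04,2.05,2.02,-0.01,-0.02,-0.03
Romania,1.12,1.57,2.28,1.65,-0.42,-0.68,-1.10
Spain,1.34,1.48,1.71,1.46,-0.14,-0.14,-0.28
Sweden,1.93,1.94,2.04,1.94,0.00,-0.10,-0.10
Mean,1.62,1.78,2.03,1.78,-0.14,-0.22,-0.36
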