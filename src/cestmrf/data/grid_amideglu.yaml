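f_amide:
- 0.0005
- 0.0009
- 0.0027
- 0.0045
- 0.0063
- 0.0081
- 0.01
k_amide:
- 50.0
- 150.0
- 300.0
- 500.0
glu_concentration:
- 2.0
- 5.0
- 10.0
- 15.0
- 20.0
- 25.0
- 30.0
k_glu:
- 4000.0
- 6000.0
- 8000.0
- 10000.0
f_ss:
- 0.02
- 0.09
- 0.16
- 0.23
- 0.3
k_ssw:
- 10.0
- 40.0
- 100.0
water_t1:
- 1.2
- 1.8
- 2.4
water_t2:
- 0.03
- 0.075
- 0.12
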