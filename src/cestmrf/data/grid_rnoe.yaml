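f_rnoe:
- 0.001
- 0.003
- 0.005
- 0.007
- 0.009
- 0.011
- 0.013
- 0.015
- 0.017
- 0.019
k_rnoe:
- 5.0
- 10.0
- 15.0
- 20.0
- 30.0
- 40.0
- 50.0
f_ss:
- 0.02
- 0.06
- 0.1
- 0.14
- 0.18
- 0.22
- 0.26
- 0.3
k_ssw:
- 10.0
- 25.0
- 40.0
- 55.0
- 70.0
- 100.0
water_t1:
- 1.2
- 1.5
- 1.8
- 2.1
- 2.4
water_t2:
- 0.03
- 0.0525
- 0.075
- 0.0975
- 0.12
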