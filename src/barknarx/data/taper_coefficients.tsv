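model	species	coefficients
STAT1	pine	0.155363	-0.344976	0.317674	-0.001186	-0.060022
STAT1	oak	0.108146	0.054412	-0.003357	-0.001480	0.488477
STAT2	pine	0.525331	-0.342769	0.310562	-0.001421	-0.407817	0.020500
STAT2	oak	0.669494	0.054381	0.003500	-0.000408	-0.644409	0.404019
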