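species	conc0_nM
PDE4B	200
b2	100
bARR	500
PKA	500
cAMP	100
AC6	1000
GsaGDP	200
GiGDP	200
RGS	100
VASP	200
PP1	100
ATP	1e+06
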