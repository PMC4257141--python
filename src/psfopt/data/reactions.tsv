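reaction_string	kon	koff	kcat
b2 + L ↔ b2L	0.0003	0.1
b2L + PKAc ↔ b2LPKAc → pb2L + PKAc	0.00026	1	5.4
pb2L → b2L			0.1
GsaGDP + b2L ↔ b2LGsaGDP → GsaGTP + b2L	0.006	0.8	0.2
GsaGTP + RGS ↔ RGSGsaGTP → GsaGDP + RGS	0.0008	1.2	16
GiGDP + pb2L ↔ pb2LGiGDP → GiGTP + pb2L	1.2	0.8	16
GiGTP + RGS ↔ RGSGiGTP → GiGDP + RGS	1.2	0.8	16
GsaGTP + AC6 ↔ AC6Gsa	0.00385	3
GiGTP + AC6Gsa ↔ AC6GsaGi	0.00385	10
AC6Gsa + PKAc ↔ AC6Gsa_PKAc → pAC6Gsa + PKAc	0.00026	1.5	30.4
pAC6Gsa + PP1 ↔ pAC6PP1 → AC6Gsa + PP1	0.0026	3	54
ATP + AC6Gsa ↔ AC6Gsa_ATP → cAMP + AC6Gsa	6e-05	10	80.42
ATP + pAC6Gsa ↔ pAC6Gsa_ATP → cAMP + pAC6Gsa	6e-05	10	8.042
ATP + AC6 ↔ AC6_ATP → cAMP + AC6	0.0001	120	0.142
cAMP + PDE4B ↔ PDE4BcAMP → AMP + PDE4B	0.03	77.44	19.36
1PKA + 2cAMP ↔ 1PKAr2c2cAMP2	3.5e-08	0.06
1PKAr2c2cAMP2 + 2cAMP ↔ 1PKAr2c2cAMP4	2.7e-07	0.28
1PKAr2cAMP4 + 2PKAc ↔ 1PKAr2c2cAMP4	8.5e-08	0.05
VASP + PKAc ↔ VASP_PKAc → pVASP + PKAc	0.00026	1.5	30.4
pVASP + PP1 ↔ pVASPPP1 → VASP + PP1	0.0026	3	54
AMP → ATP			1
ATP + AC6GsaGi ↔ AC6GsaGi_ATP → cAMP + AC6GsaGi	6e-05	10	1
b2L + bARR ↔ b2LbARR	0.0006	0.1
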