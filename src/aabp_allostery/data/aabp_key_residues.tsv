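# Per-residue MM-GBSA binding-energy decomposition (kJ/mol) for the three
# AABP-substrate complexes; consensus residue numbers with native labels.
system	residue	E_VDW	E_ELE	E_GB	E_GBSUR	E_TOT
GlnBP	117 (K115)	-0.44 ± 0.31	-6.97 ± 4.61	1.33 ± 3.8	-0.02 ± 0.02	-6.10 ± 0.52
GlnBP	161 (D157)	-0.69 ± 0.8	-3.89 ± 3.44	2.57 ± 0.19	-0.04 ± 0.02	-2.04 ± 1.35
GlnBP	69 (A67)	-0.23 ± 0.33	-2.92 ± 0.37	1.53 ± 0.34	-0.02 ± 0.01	-1.64 ± 0.39
GlnBP	11 (D10)	-0.45 ± 0.01	-2.70 ± 0.22	1.72 ± 0.22	0.01 ± 0.00	-1.43 ± 0.01
GlnBP	70 (G68)	-0.54 ± 0.01	-1.99 ± 1.32	1.24 ± 0.37	-0.03 ± 0.01	-1.33 ± 0.45
GlnBP	121 (G119)	-0.22 ± 0.13	-1.61 ± 0.26	0.75 ± 0.25	-0.06 ± 0.01	-1.14 ± 0.12
HisJ	11 (D11)	0.11 ± 0.09	-9.80 ± 0.45	5.11 ± 0.56	-0.05 ± 0	-4.63 ± 0.02
HisJ	117 (L117)	-1.44 ± 0.06	-1.24 ± 1.70	0.90 ± 0.02	-0.07 ± 0.03	-1.85 ± 0.38
HisJ	69 (S69)	-0.37 ± 0.41	-1.13 ± 0.91	-0.14 ± 0.29	-0.05 ± 0.02	-1.68 ± 0.23
HisJ	14 (Y14)	-1.26 ± 0.09	-0.56 ± 0.90	0.43 ± 0.36	-0.08 ± 0.02	-1.45 ± 0.66
HisJ	52 (L52)	-0.95 ± 0.19	-0.09 ± 0.02	0.16 ± 0.01	-0.12 ± 0.01	-1.01 ± 0.17
LAOBP	117 (L117)	-0.91 ± 0	0.40 ± 0.33	-1.64 ± 0.14	-0.08 ± 0.01	-2.26 ± 0.16
LAOBP	11 (D11)	-0.59 ± 0.18	-1.73 ± 0.04	0.21 ± 0.06	0.05 ± 0.02	-2.11 ± 0.23
LAOBP	52 (F52)	-1.5 ± 0.07	-0.57 ± 0.04	0.17 ± 0.08	-0.07 ± 0.01	-1.98 ± 0.01
LAOBP	72 (S72)	-1.17 ± 0.03	-0.86 ± 0.50	0.11 ± 0.04	-0.03 ± 0	-1.94 ± 0.09
LAOBP	77 (R77)	-0.06 ± 0.04	-1.08 ± 0.50	-0.41 ± 0.02	-0.01 ± 0.01	-1.56 ± 0.16
LAOBP	70 (S70)	-1.12 ± 0.08	-0.38 ± 0.01	0.40 ± 0.01	0.06 ± 0.02	-1.04 ± 0.26
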