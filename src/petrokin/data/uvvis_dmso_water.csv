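# Petrosamine UV-vis band maxima and molar absorptivities in DMSO-H2O mixtures.
# Band 1 = dominant pi-pi* transition; band 2 = long-wavelength n-pi* transition.
# Epsilon values normalized to the literature value eps = 4700 at lambda_max2 in 100% H2O.
water_pct,lmax1_nm,eps1,lmax2_nm,eps2
0,296,184000,648,24000
20,290,172000,622,20600
40,288,161000,604,19400
60,287,141700,589,16500
80,282,122252,581,12900
100,281,68500,570,4700
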