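# Representative (synthetic stand-in) chromophore absorption table.
# Columns: absorption coefficient in 1/mm per unit volume fraction;
# hbo2/hhb refer to fully oxygenated / deoxygenated whole blood.
# Values follow literature-scale near-infrared trends and are intended for
# phantom generation, not for quantitative spectroscopy.
wavelength_nm,hbo2,hhb,water,fat
600,1.72,7.88,0.00022,0.0009
625,0.40,3.10,0.00028,0.0008
650,0.20,2.01,0.00032,0.0007
675,0.16,1.45,0.00045,0.0007
700,0.16,0.96,0.00060,0.0008
725,0.20,0.79,0.00130,0.0009
750,0.31,0.75,0.00260,0.0010
775,0.37,0.56,0.00240,0.0010
800,0.44,0.41,0.00200,0.0011
825,0.51,0.39,0.00290,0.0012
850,0.57,0.37,0.00430,0.0014
875,0.60,0.39,0.00560,0.0018
900,0.64,0.41,0.00680,0.0030
925,0.65,0.40,0.01200,0.0110
950,0.65,0.38,0.02600,0.0060
975,0.64,0.36,0.04300,0.0050
1000,0.63,0.35,0.03600,0.0048
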