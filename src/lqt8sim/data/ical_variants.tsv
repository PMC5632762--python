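# L-type calcium current (I_CaL) variant parameter sets for CACNA1C alleles.
# Columns: label <TAB> csf <TAB> va_half <TAB> sa <TAB> vina_half <TAB> sina <TAB> tcsf <TAB> provenance
# csf: conductance scale factor (dimensionless, vs WT TP06 g_CaL)
# va_half/sa: steady-state activation midpoint (mV) / slope factor (mV)
# vina_half/sina: steady-state voltage-inactivation midpoint (mV) / slope factor (mV)
# tcsf: scale factor on the voltage-inactivation time constant (dimensionless)
# WT kinetics are the unmodified TP06 d/f gate curves (midpoints -8 / -20 mV,
# slopes 7.5 / 7 mV). R858H carries the experimentally reported ~2 mV negative
# shift of activation and ~2 mV positive shift of inactivation. csf values for
# all non-WT alleles were calibrated with lqt8sim.ical_variants.calibrate_csf so
# that the voltage-clamp I-V minimum reproduces the experimental peak-density
# fold ratio vs WT (0.86, 1.04, 1.08, 1.19, 1.54); see the provenance column.
label	csf	va_half	sa	vina_half	sina	tcsf	provenance
G1783C	0.842945	-8.0	7.5	-20.0	7.0	1.0	csf calibrated to 0.86-fold peak density
WT	1.0	-8.0	7.5	-20.0	7.0	1.0	unmodified TP06
P381S	1.046141	-8.0	7.5	-20.0	7.0	1.0	csf calibrated to 1.04-fold peak density
M456I	1.092253	-8.0	7.5	-20.0	7.0	1.0	csf calibrated to 1.08-fold peak density
A582D	1.222356	-8.0	7.5	-20.0	7.0	1.0	csf calibrated to 1.19-fold peak density
R858H	1.567050	-10.0	7.5	-18.0	7.0	1.0	csf calibrated to 1.54-fold peak density; +/-2 mV kinetic shifts
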