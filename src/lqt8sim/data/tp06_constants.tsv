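# TP06 human ventricular myocyte model constants.
# Columns: name <TAB> value <TAB> unit <TAB> note
# Published values of the ten Tusscher-Panfilov 2006 model (CellML distribution);
# SR release/leak constants belong to the calcium-induced-calcium-release flux
# formulated as the combination of SR release and SR leak.
R	8314.472	mJ/(mol*K)	gas constant
T	310.0	K	temperature
F	96485.3415	C/mol	Faraday constant
Cm	0.185	uF	whole-cell capacitance used in concentration bookkeeping
V_c	0.016404	um3*1e6	cytoplasmic volume
V_sr	0.001094	um3*1e6	sarcoplasmic reticulum volume
V_ss	0.00005468	um3*1e6	dyadic subspace volume
K_o	5.4	mM	extracellular potassium
Na_o	140.0	mM	extracellular sodium
Ca_o	2.0	mM	extracellular calcium
g_Na	14.838	nS/pF	fast sodium conductance
g_K1	5.405	nS/pF	inward rectifier conductance
g_Kr	0.153	nS/pF	rapid delayed rectifier conductance
g_Ks_epi	0.392	nS/pF	slow delayed rectifier, epicardial
g_Ks_endo	0.392	nS/pF	slow delayed rectifier, endocardial
g_Ks_m	0.098	nS/pF	slow delayed rectifier, midmyocardial
g_to_epi	0.294	nS/pF	transient outward, epicardial
g_to_endo	0.073	nS/pF	transient outward, endocardial
g_to_m	0.294	nS/pF	transient outward, midmyocardial
g_CaL	0.0000398	L/(F*ms)	L-type calcium conductance scale
g_bna	0.00029	nS/pF	background sodium conductance
g_bca	0.000592	nS/pF	background calcium conductance
g_pCa	0.1238	pA/pF	sarcolemmal calcium pump maximum
K_pCa	0.0005	mM	calcium pump half-saturation
g_pK	0.0146	nS/pF	plateau potassium conductance
P_kna	0.03	dimensionless	Na/K permeability ratio for IKs reversal
P_NaK	2.724	pA/pF	Na/K pump maximum
K_mk	1.0	mM	pump K half-saturation
K_mNa	40.0	mM	pump Na half-saturation
K_NaCa	1000.0	pA/pF	Na/Ca exchanger maximum
K_sat	0.1	dimensionless	NCX saturation factor
alpha_ncx	2.5	dimensionless	NCX outward-mode factor
gamma_ncx	0.35	dimensionless	NCX voltage-dependence position
Km_Ca	1.38	mM	NCX Ca half-saturation
Km_Nai	87.5	mM	NCX Na half-saturation
V_rel	0.102	mM/ms	maximal SR release rate
k1_prime	0.15	1/(mM^2*ms)	release activation rate scale
k2_prime	0.045	1/(mM*ms)	release inactivation rate scale
k3	0.060	1/ms	release deactivation rate
k4	0.005	1/ms	release-gate recovery rate
EC_sr	1.5	mM	half-saturation of SR-load regulation
max_sr	2.5	dimensionless	SR-load regulation ceiling
min_sr	1.0	dimensionless	SR-load regulation floor
V_leak	0.00036	1/ms	SR leak rate (routed into the dyadic subspace with the release flux)
S_over	1500.0	dimensionless	release-gate sensitization above the overload threshold (calibrated; enables spontaneous release)
K_over	3.97	mM	SR load threshold for overload sensitization (calibrated to the afterdepolarization phenotype)
w_over	0.005	mM	width of the overload threshold sigmoid
V_xfer	0.0038	1/ms	subspace-to-cytosol transfer rate
Vmax_up	0.006375	mM/ms	SERCA uptake maximum
K_up	0.00025	mM	SERCA half-saturation
Buf_c	0.2	mM	cytoplasmic buffer concentration
K_buf_c	0.001	mM	cytoplasmic buffer half-saturation
Buf_sr	10.0	mM	SR buffer concentration
K_buf_sr	0.3	mM	SR buffer half-saturation
Buf_ss	0.4	mM	subspace buffer concentration
K_buf_ss	0.00025	mM	subspace buffer half-saturation
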