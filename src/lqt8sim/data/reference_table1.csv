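# Published summary values for the six CACNA1C alleles (provenance: printed
# results table and results text of the source study). Units per row.
quantity,units,G1783C,WT,P381S,M456I,A582D,R858H
ical_density_fold,percent,86,100,104,108,119,154
casr_max_endo,mM,2.54,2.68,2.82,2.94,3.17,3.51
cai_amp_endo,mM,3.6e-4,4.0e-4,4.5e-4,4.9e-4,5.7e-4,7.0e-4
resting_potential_endo,mV,-85.87,-85.83,-85.80,-85.75,-85.67,-85.58
apd90_endo,ms,264.4,267.8,271.8,277,282.6,294
apdr_max_slope_endo,dimensionless,1.02,1.08,1.1,1.15,1.15,1.35
cv,mm/ms,0.344,0.344,0.344,0.344,0.344,0.344
mpcl,ms,350,352,354,356,365,370
t_wave_width,ms,60,59.9,59.9,61.7,63.9,64.5
qt_interval,ms,397.1,398.5,401.2,408.2,415.9,425.7
rt,ms,360.48,363.6,367.34,374.84,381.14,393.32
dor,ms,60.94,61.3,62.2,64.12,65.64,67.96
msg_epi_m,ms/mm,18,18.1,18.5,18.9,19.2,19.5
t_wave_amplitude,mV,1.051,1.053,1.056,1.075,1.087,1.104
delta_epi_m_max,mV,73.8,74.2,75.2,75.6,77.1,79.4
delta_endo_m_max,mV,91.59,92.06,93.06,93.14,94.69,96.27
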