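group,delta_biomass_density,delta_biomass_density_se,delta_socd,delta_socd_se,delta_tocd,delta_tocd_se,biomass_total_tg,biomass_total_tg_se,soc_total_tg,soc_total_tg_se,toc_total_tg,toc_total_tg_se
P_koraiensis,8.98,0.53,4.20,0.09,13.18,0.62,22.29,1.34,11.26,0.17,33.55,1.51
L_gmelinii,7.54,0.31,3.78,0.08,11.32,0.39,236.97,13.93,109.87,1.80,346.84,15.73
P_sylvestris,3.25,0.52,0.95,0.28,4.20,0.80,14.96,1.95,4.05,0.21,19.01,2.16
P_tabuliformis,0.54,0.10,1.28,0.05,1.82,0.15,8.61,1.52,17.70,0.58,26.31,2.10
Populus,4.86,0.20,0.73,0.11,5.59,0.31,227.36,7.93,59.89,4.30,287.25,12.23
other,6.07,0.30,0.91,0.03,6.98,0.33,168.05,11.30,32.17,1.94,200.22,13.24
Total,,,,,,,678.25,37.98,234.94,9.60,913.19,47.58
Average,5.51,0.31,1.91,0.08,7.42,0.39,,,,,,
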