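material,d2H_ne_carbon,sd_carbon,d2H_ne_chromium,sd_chromium,x_e_carbon,sd_xe_carbon,x_e_chromium,sd_xe_chromium,n_pct,diff
Beech wood,-118.1,1.7,-117.5,2.0,0.15,0.01,0.12,0.03,0.20,-0.6
Algae,-112.7,0.7,-107.5,2.6,0.26,0.01,0.27,0.02,1.27,-5.2
Leaves,-107.5,3.7,-107.8,2.5,0.19,0.01,0.19,0.01,2.94,0.3
Fungus,-27.2,1.4,-25.7,1.5,0.29,0.01,0.27,0.01,4.67,-1.5
Insect,-121.3,1.4,-125.2,1.5,0.17,0.01,0.14,0.01,10.42,3.9
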