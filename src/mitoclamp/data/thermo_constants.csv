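condition_label,pH,temperature_K,K_CK_apparent,dG0_ATP_kcal_mol,citation
buffer_z_pH7.1_37C_Mg,7.1,310.15,177.0,-8.11,"Apparent CK equilibrium constant for Mg-containing media near pH 7.1 at 37 C (Golding/Teague-style apparent-equilibrium treatment); dG0'_ATP calibrated so the resting-demand clamp composition (ATP 5, Cr 5, PCr 30, Pi 10 mM) evaluates to -15.24 kcal/mol"
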