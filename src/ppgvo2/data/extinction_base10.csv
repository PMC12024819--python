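wavelength_nm,eps_hb,eps_hbo2
670,2795.12,294.00
770,1344.20,650.00
810,717.08,865.00
850,691.32,1058.00
950,714.08,1204.00
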