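atc_code,daily_dose_pills,note
J05AR,1.0,fixed-dose combinations once daily
J05AG,1.0,NNRTIs (efavirenz/nevirapine-class) assumed once daily maintenance
J05AE,2.0,protease inhibitors assumed twice daily
J05AJ,1.0,integrase inhibitors once daily
J05AX,1.0,other antivirals once daily
J05AF,1.0,single NRTIs once daily (not counted as ART by default prefix list)
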