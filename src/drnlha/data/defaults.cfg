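# drnlha circuit parameters (pA, Hz, s; J in pA/Hz, g in Hz/pA)
g.5HT = 0.033
g.GABA_DRN = 0.061
g.Ox = 0.205
g.GABA_LHA = 0.195
I0.5HT = 0.13
I0.GABA_DRN = 0.0
I0.Ox = 0.0
I0.GABA_LHA = 0.0
I_bg.5HT = 231.47
I_bg.GABA_DRN = 246.0
I_bg.Ox = 617.6
I_bg.GABA_LHA = 20.9
J.5HT_auto = 16.0
J.Ox_to_5HT = 15.0
J.5HT_to_GABA_DRN = 10.0
J.Ox_to_GABA_DRN = 5.0
J.Ox_auto = 6.0
J.5HT_to_Ox = 6.0
J.Ox_to_GABA_LHA = 0.0
J.5HT_to_GABA_LHA = 6.0
J.GABA_DRN_to_5HT = 5.0
J.GABA_DRN_to_GABA_DRN = 5.0
J.GABA_LHA_to_Ox = 118.0
J.GABA_LHA_to_GABA_LHA = 5.0
tau.5HT_auto = 1.0
tau.Ox_to_5HT = 60.0
tau.5HT_to_GABA_DRN = 60.0
tau.Ox_to_GABA_DRN = 5.0
tau.Ox_auto = 10.0
tau.5HT_to_Ox = 2.0
tau.Ox_to_GABA_LHA = 10.0
tau.5HT_to_GABA_LHA = 2.0
sign.5HT_to_GABA_LHA = 1
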