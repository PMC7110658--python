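# Published reference system failure probabilities and reliability indices for the
# whole vertebral column, by condition and body mass. Used as calibration targets
# for the synthetic demand generator and as the acceptance surface for recovery.
condition,body_mass_kg,pf,beta
normal,30,2.05e-5,4.10
normal,40,2.57e-5,4.05
normal,50,3.75e-5,3.96
normal,60,4.93e-5,3.89
normal,70,6.59e-5,3.82
normal,80,8.82e-5,3.75
scoliosis,30,2.77e-4,3.45
scoliosis,40,1.14e-3,3.05
scoliosis,50,1.82e-3,2.91
scoliosis,60,2.22e-3,2.85
scoliosis,70,2.45e-3,2.81
scoliosis,80,3.18e-3,2.73
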