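# Prony-series viscoelastic constants of the intervertebral disc tissues
# (metadata only: stored and validated, never solved in this package).
# g_i: shear relaxation weight, k_i: bulk relaxation weight, tau_i: relaxation time (s).
# The source prints the nucleus bulk weights as 0.0 for every term.
tissue,E_mpa,poisson,term,g,k,tau_s
annulus,8.0,0.45,1,0.399,0.399,3.45
annulus,8.0,0.45,2,0.000,0.300,100
annulus,8.0,0.45,3,0.361,0.149,1000
annulus,8.0,0.45,4,0.108,0.150,5000
nucleus,2.0,0.49,1,0.638,0.0,0.141
nucleus,2.0,0.49,2,0.156,0.0,2.21
nucleus,2.0,0.49,3,0.120,0.0,39.9
nucleus,2.0,0.49,4,0.0383,0.0,266
nucleus,2.0,0.49,5,0.0,0.0,500
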