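# Yield-stress statistical parameters (MPa) for the four spinal load-bearing tissues.
# Vertebral rows: the source table prints the cortical tension/compression cells run
# together as "7513.9817628.4"; transcribed by column structure as tension mean 75,
# tension std 13.98, compression mean 176, compression std 28.4. Not reinterpreted.
# Nucleus tension and compression share the same published mean/std.
tissue,mode,mean_mpa,std_mpa
cortical,tension,75,13.98
cortical,compression,176,28.4
cancellous,tension,1.9,0.86
cancellous,compression,1.78,0.58
annulus,tension,7.30,2.30
annulus,compression,3.65,1.15
nucleus,tension,0.260,0.0819
nucleus,compression,0.260,0.0819
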