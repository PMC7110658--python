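# Deterministic orthotropic elastic constants of vertebral bone (metadata only:
# carried for a future FEM-backed demand stage, consumed by no computation here).
tissue,E_xx_mpa,E_yy_mpa,E_zz_mpa,G_xy_mpa,G_yz_mpa,G_xz_mpa,v_xy,v_yz,v_xz
cortical,11300,11300,22000,3800,5400,5400,0.484,0.203,0.203
cancellous,140,140,200,48.3,48.3,48.3,0.450,0.315,0.250
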