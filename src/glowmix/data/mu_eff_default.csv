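wavelength_nm,mu_eff_per_mm
400,2.6
450,2.3
500,1.9
530,1.95
542,2.10
560,1.55
576,2.05
590,1.70
600,0.95
608,0.45
615,0.33
620,0.30
640,0.285
660,0.27
680,0.255
700,0.225
720,0.22
760,0.215
800,0.21
900,0.205
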