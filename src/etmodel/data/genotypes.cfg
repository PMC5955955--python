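; Shipped synthetic Kv2 (Shab) genotype parameter sets.
; These are the package's own calibration: they are constrained to
; reproduce the qualitative genotype pattern (non-inactivating native
; current; hKv9.2 left-shifts activation and adds inactivation; the
; D379E mutant inactivates more completely and faster), not any
; particular cell's fitted values.  Units: nS, mV, ms.

[native_shab]
gmax = 30.0
E = -90.0
P = 4
Q = 0
act.Vh = -20.0
act.k = 9.0
act.Amp = 15.0
act.Vmax = -50.0
act.sigma = 40.0

[shab_hkv92]
gmax = 30.0
E = -90.0
P = 4
Q = 1
act.Vh = -32.0
act.k = 9.0
act.Amp = 15.0
act.Vmax = -50.0
act.sigma = 40.0
inact.Vh = -55.0
inact.k = 6.0
inact.Amp = 400.0
inact.Vmax = -40.0
inact.sigma = 60.0

[shab_hkv92_d379e]
gmax = 30.0
E = -90.0
P = 4
Q = 1
act.Vh = -32.0
act.k = 9.0
act.Amp = 15.0
act.Vmax = -50.0
act.sigma = 40.0
inact.Vh = -55.0
inact.k = 4.0
inact.Amp = 250.0
inact.Vmax = -40.0
inact.sigma = 80.0
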