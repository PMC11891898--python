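# Shear viscosity of TIP3P water (periodic-perturbation MD) and of
# experimental water, mPa s, as a function of temperature.  Simulation /
# experimental inputs shipped verbatim; not recomputed by this package.
T_K	tip3p_mPas	tip3p_err_mPas	expt_mPas
273.15	0.445	0.005	1.793
278.15	0.412	0.007	1.518
283.15	0.388	0.003	1.307
288.15	0.355	0.004	1.137
293.15	0.337	0.003	1.002
298.15	0.319	0.004	0.890
303.15	0.299	0.005	0.798
308.15	0.283	0.004	0.719
313.15	0.273	0.006	0.653
318.15	0.254	0.003	0.596
323.15	0.244	0.002	0.547
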