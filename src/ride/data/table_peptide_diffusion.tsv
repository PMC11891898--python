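# Infinitely dilute diffusion coefficients (1e-5 cm^2/s) and finite-size
# correction parameters alpha for ACE/NME-capped mono- and decapeptides in
# TIP3P water at 310.15 K.  MD-derived inputs shipped verbatim; not
# recomputed by this package.
aa	d0_mono	d0_mono_err	alpha_mono	alpha_mono_err	d0_deca	d0_deca_err	alpha_deca	alpha_deca_err
GLY	2.68	0.08	1.07	0.02	1.40	0.04	0.874	0.009
ALA	2.44	0.06	1.01	0.02	1.27	0.05	0.91	0.01
SER	2.23	0.07	0.81	0.02	1.28	0.04	0.96	0.01
PRO	2.39	0.02	1.009	0.004	1.16	0.06	0.84	0.02
VAL	2.19	0.03	0.891	0.008	1.15	0.01	0.843	0.003
THR	2.25	0.03	0.999	0.008	1.18	0.05	0.86	0.02
CYS	2.28	0.06	0.85	0.01	1.24	0.05	0.82	0.01
ILE	2.15	0.02	0.954	0.005	1.09	0.03	0.73	0.03
LEU	2.07	0.05	0.87	0.01	1.11	0.04	0.81	0.01
ASP	2.01	0.07	0.91	0.02	1.03	0.03	0.881	0.008
ASN	2.10	0.03	0.848	0.009	1.12	0.01	0.821	0.003
GLU	1.93	0.05	0.95	0.02	1.00	0.05	0.95	0.01
GLN	2.08	0.03	1.00	0.01	1.06	0.03	0.826	0.008
LYS	1.93	0.05	0.91	0.02	0.93	0.01	0.811	0.004
MET	2.07	0.03	0.85	0.01	1.14	0.01	0.872	0.003
HIS	1.99	0.02	0.909	0.006	1.09	0.03	0.960	0.007
PHE	2.03	0.04	0.892	0.005	1.08	0.07	0.824	0.008
ARG	1.87	0.02	0.92	0.01	0.88	0.02	0.89	0.02
TYR	1.93	0.03	0.913	0.006	1.03	0.02	0.707	0.006
TRP	1.91	0.02	0.892	0.009	1.07	0.03	0.915	0.005
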