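# mdscatter neutron & X-ray species table
# provenance: coherent/incoherent neutron scattering lengths (fm) from Sears,
#   Neutron News 3(3) (1992); X-ray Cromer-Mann 4-Gaussian coefficients from
#   International Tables for Crystallography Vol. C, Table 6.1.1.4; van der
#   Waals radii (Angstrom) from Bondi, J. Phys. Chem. 68 (1964) 441.
# columns: label b_coh b_inc a1 b1 a2 b2 a3 b3 a4 b4 c r_vdw
H	-3.7390	25.274	0.489918	20.6593	0.262003	7.74039	0.196767	49.5519	0.049879	2.20159	0.001305	1.20
D	6.6710	4.04	0.489918	20.6593	0.262003	7.74039	0.196767	49.5519	0.049879	2.20159	0.001305	1.20
C	6.6460	0.0	2.31000	20.8439	1.02000	10.2075	1.58860	0.568700	0.865000	51.6512	0.215600	1.70
N	9.3600	2.0	12.2126	0.005700	3.13220	9.89330	2.01250	28.9975	1.16630	0.582600	-11.529	1.55
O	5.8030	0.0	3.04850	13.2771	2.28680	5.70110	1.54630	0.323900	0.867000	32.9089	0.250800	1.52
P	5.1300	0.2	6.43450	1.90670	4.17910	27.1570	1.78000	0.526000	1.49080	68.1645	1.11490	1.80
S	2.8470	0.0	6.90530	1.46790	5.20340	22.2151	1.43790	0.253600	1.58630	56.1720	0.866900	1.80
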