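preset	response	Na	K	K(A)	K(Ca)	H	Ca(L)	Ca(T)	CAN
fig2A	non-accommodating	0.02	0.01	0.01	-	0.002	-	-	-
fig2B	accommodating	0.01	0.001	0.005	-	0.001	-	4.00e-4	-
fig2C	single-spike	0.01	0.002	0.02	-	-	-	2.00e-4	-
fig2D	irregular	0.02	0.01	0.01	-	0.005	-	1.00e-4	-
fig3A	LTS-single-AP	0.01	0.1	0.1	-	3.58e-5	-	0.005	-
fig3B	LTS-burst	0.011	0.075	0.025	-	3.58e-5	-	0.002	-
fig3C	plateau	0.004	0.007	0.001	0.001	0.0005	0.001	0.0001	0.00128
fig3D	plateau	0.004	0.007	0.001	0.001	0.0005	0.001	-	0.00128
fig3E	plateau	0.004	0.006	0.001	0.001	0.0005	0.001	0.0001	0.00128
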