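circuit	seed	fitness
circuit_000	2026	0.8512
circuit_001	2027	0.8619
circuit_002	2028	0.7642
circuit_003	2029	0.8592
circuit_004	2030	0.8707
circuit_005	2031	0.8676
circuit_006	2033	0.8669
circuit_007	2035	0.8657
circuit_008	2036	0.8389
circuit_009	2037	0.8428
circuit_010	2038	0.8569
circuit_011	2039	0.8702
circuit_012	2040	0.8286
circuit_013	2041	0.8722
circuit_014	2042	0.7985
circuit_015	2043	0.8658
circuit_016	2044	0.8554
circuit_017	2045	0.862
best	2030	0.8707
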