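# SYNTHETIC per-MO table for adenine (Z=70, 35 MOs).
# Stand-in for an unpublished RHF/3-21G + Mulliken analysis; preserves MO count,
# electron count, atomic composition and the experimental Koopmans HOMO energy.
n_1s_core	-425.00	N_1s:2.0000
n_1s_core	-425.00	N_1s:2.0000
n_1s_core	-425.00	N_1s:2.0000
n_1s_core	-425.00	N_1s:2.0000
n_1s_core	-425.00	N_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
v1	-38.00	C_2p:0.1875;C_2s:0.7187;H_1s:0.0938;N_2p:0.2813;N_2s:0.7187
v2	-36.35	C_2p:0.2055;C_2s:0.6918;H_1s:0.1027;N_2p:0.3082;N_2s:0.6918
v3	-34.72	C_2p:0.2235;C_2s:0.6647;H_1s:0.1118;N_2p:0.3353;N_2s:0.6647
v4	-33.12	C_2p:0.2417;C_2s:0.6375;H_1s:0.1208;N_2p:0.3625;N_2s:0.6375
v5	-31.55	C_2p:0.2599;C_2s:0.6101;H_1s:0.1300;N_2p:0.3899;N_2s:0.6101
v6	-30.00	C_2p:0.2782;C_2s:0.5827;H_1s:0.1391;N_2p:0.4173;N_2s:0.5827
v7	-28.49	C_2p:0.2966;C_2s:0.5551;H_1s:0.1483;N_2p:0.4449;N_2s:0.5551
v8	-27.00	C_2p:0.3150;C_2s:0.5275;H_1s:0.1575;N_2p:0.4725;N_2s:0.5275
v9	-25.54	C_2p:0.3334;C_2s:0.4999;H_1s:0.1667;N_2p:0.5001;N_2s:0.4999
v10	-24.11	C_2p:0.3517;C_2s:0.4724;H_1s:0.1759;N_2p:0.5276;N_2s:0.4724
v11	-22.72	C_2p:0.3701;C_2s:0.4449;H_1s:0.1850;N_2p:0.5551;N_2s:0.4449
v12	-21.36	C_2p:0.3883;C_2s:0.4175;H_1s:0.1942;N_2p:0.5825;N_2s:0.4175
v13	-20.04	C_2p:0.4064;C_2s:0.3904;H_1s:0.2032;N_2p:0.6096;N_2s:0.3904
v14	-18.75	C_2p:0.4243;C_2s:0.3635;H_1s:0.2122;N_2p:0.6365;N_2s:0.3635
v15	-17.51	C_2p:0.4420;C_2s:0.3370;H_1s:0.2210;N_2p:0.6630;N_2s:0.3370
v16	-16.30	C_2p:0.4594;C_2s:0.3109;H_1s:0.2297;N_2p:0.6891;N_2s:0.3109
v17	-15.15	C_2p:0.4765;C_2s:0.2853;H_1s:0.2382;N_2p:0.7147;N_2s:0.2853
v18	-14.04	C_2p:0.4931;C_2s:0.2604;H_1s:0.2465;N_2p:0.7396;N_2s:0.2604
v19	-12.99	C_2p:0.5091;C_2s:0.2363;H_1s:0.2546;N_2p:0.7637;N_2s:0.2363
v20	-12.00	C_2p:0.5245;C_2s:0.2132;H_1s:0.2623;N_2p:0.7868;N_2s:0.2132
v21	-11.07	C_2p:0.5391;C_2s:0.1914;H_1s:0.2695;N_2p:0.8086;N_2s:0.1914
v22	-10.22	C_2p:0.5526;C_2s:0.1711;H_1s:0.2763;N_2p:0.8289;N_2s:0.1711
v23	-9.47	C_2p:0.5648;C_2s:0.1528;H_1s:0.2824;N_2p:0.8472;N_2s:0.1528
v24	-8.84	C_2p:0.5751;C_2s:0.1374;H_1s:0.2875;N_2p:0.8626;N_2s:0.1374
v25	-8.44	C_2p:0.5817;C_2s:0.1274;H_1s:0.2909;N_2p:0.8726;N_2s:0.1274
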