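# SYNTHETIC per-MO table for thymine (Z=66, 33 MOs).
# Stand-in for an unpublished RHF/3-21G + Mulliken analysis; preserves MO count,
# electron count, atomic composition and the experimental Koopmans HOMO energy.
o_1s_core	-540.00	O_1s:2.0000
o_1s_core	-540.00	O_1s:2.0000
n_1s_core	-425.00	N_1s:2.0000
n_1s_core	-425.00	N_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
v1	-38.00	C_2p:0.2045;C_2s:0.7702;H_1s:0.1227;N_2p:0.1227;N_2s:0.3081;O_2p:0.1636;O_2s:0.3081
v2	-36.32	C_2p:0.2241;C_2s:0.7375;H_1s:0.1345;N_2p:0.1345;N_2s:0.2950;O_2p:0.1793;O_2s:0.2950
v3	-34.66	C_2p:0.2438;C_2s:0.7048;H_1s:0.1463;N_2p:0.1463;N_2s:0.2819;O_2p:0.1950;O_2s:0.2819
v4	-33.04	C_2p:0.2633;C_2s:0.6722;H_1s:0.1580;N_2p:0.1580;N_2s:0.2689;O_2p:0.2107;O_2s:0.2689
v5	-31.44	C_2p:0.2829;C_2s:0.6396;H_1s:0.1697;N_2p:0.1697;N_2s:0.2558;O_2p:0.2263;O_2s:0.2558
v6	-29.87	C_2p:0.3024;C_2s:0.6071;H_1s:0.1814;N_2p:0.1814;N_2s:0.2429;O_2p:0.2419;O_2s:0.2429
v7	-28.33	C_2p:0.3218;C_2s:0.5748;H_1s:0.1931;N_2p:0.1931;N_2s:0.2299;O_2p:0.2574;O_2s:0.2299
v8	-26.82	C_2p:0.3411;C_2s:0.5427;H_1s:0.2046;N_2p:0.2046;N_2s:0.2171;O_2p:0.2728;O_2s:0.2171
v9	-25.35	C_2p:0.3602;C_2s:0.5108;H_1s:0.2161;N_2p:0.2161;N_2s:0.2043;O_2p:0.2882;O_2s:0.2043
v10	-23.91	C_2p:0.3792;C_2s:0.4792;H_1s:0.2275;N_2p:0.2275;N_2s:0.1917;O_2p:0.3033;O_2s:0.1917
v11	-22.50	C_2p:0.3979;C_2s:0.4479;H_1s:0.2388;N_2p:0.2388;N_2s:0.1791;O_2p:0.3184;O_2s:0.1791
v12	-21.13	C_2p:0.4165;C_2s:0.4170;H_1s:0.2499;N_2p:0.2499;N_2s:0.1668;O_2p:0.3332;O_2s:0.1668
v13	-19.80	C_2p:0.4347;C_2s:0.3866;H_1s:0.2608;N_2p:0.2608;N_2s:0.1546;O_2p:0.3478;O_2s:0.1546
v14	-18.51	C_2p:0.4526;C_2s:0.3568;H_1s:0.2716;N_2p:0.2716;N_2s:0.1427;O_2p:0.3621;O_2s:0.1427
v15	-17.27	C_2p:0.4701;C_2s:0.3276;H_1s:0.2821;N_2p:0.2821;N_2s:0.1310;O_2p:0.3761;O_2s:0.1310
v16	-16.08	C_2p:0.4872;C_2s:0.2992;H_1s:0.2923;N_2p:0.2923;N_2s:0.1197;O_2p:0.3897;O_2s:0.1197
v17	-14.93	C_2p:0.5037;C_2s:0.2716;H_1s:0.3022;N_2p:0.3022;N_2s:0.1087;O_2p:0.4030;O_2s:0.1087
v18	-13.84	C_2p:0.5196;C_2s:0.2451;H_1s:0.3118;N_2p:0.3118;N_2s:0.0981;O_2p:0.4157;O_2s:0.0981
v19	-12.82	C_2p:0.5347;C_2s:0.2199;H_1s:0.3208;N_2p:0.3208;N_2s:0.0879;O_2p:0.4278;O_2s:0.0879
v20	-11.86	C_2p:0.5490;C_2s:0.1961;H_1s:0.3294;N_2p:0.3294;N_2s:0.0784;O_2p:0.4392;O_2s:0.0784
v21	-10.99	C_2p:0.5622;C_2s:0.1741;H_1s:0.3373;N_2p:0.3373;N_2s:0.0696;O_2p:0.4498;O_2s:0.0696
v22	-10.21	C_2p:0.5740;C_2s:0.1544;H_1s:0.3444;N_2p:0.3444;N_2s:0.0617;O_2p:0.4592;O_2s:0.0617
v23	-9.56	C_2p:0.5840;C_2s:0.1378;H_1s:0.3504;N_2p:0.3504;N_2s:0.0551;O_2p:0.4672;O_2s:0.0551
v24	-9.14	C_2p:0.5904;C_2s:0.1271;H_1s:0.3543;N_2p:0.3543;N_2s:0.0508;O_2p:0.4723;O_2s:0.0508
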