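# SYNTHETIC per-MO table for cytosine (Z=58, 29 MOs).
# Stand-in for an unpublished RHF/3-21G + Mulliken analysis; preserves MO count,
# electron count, atomic composition and the experimental Koopmans HOMO energy.
o_1s_core	-540.00	O_1s:2.0000
n_1s_core	-425.00	N_1s:2.0000
n_1s_core	-425.00	N_1s:2.0000
n_1s_core	-425.00	N_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
v1	-38.00	C_2p:0.1851;C_2s:0.6992;H_1s:0.1157;N_2p:0.2082;N_2s:0.5244;O_2p:0.0925;O_2s:0.1748
v2	-36.06	C_2p:0.2057;C_2s:0.6657;H_1s:0.1286;N_2p:0.2314;N_2s:0.4993;O_2p:0.1029;O_2s:0.1664
v3	-34.15	C_2p:0.2263;C_2s:0.6322;H_1s:0.1415;N_2p:0.2546;N_2s:0.4741;O_2p:0.1132;O_2s:0.1580
v4	-32.28	C_2p:0.2470;C_2s:0.5986;H_1s:0.1544;N_2p:0.2779;N_2s:0.4490;O_2p:0.1235;O_2s:0.1497
v5	-30.44	C_2p:0.2676;C_2s:0.5651;H_1s:0.1673;N_2p:0.3011;N_2s:0.4238;O_2p:0.1338;O_2s:0.1413
v6	-28.65	C_2p:0.2882;C_2s:0.5317;H_1s:0.1801;N_2p:0.3242;N_2s:0.3988;O_2p:0.1441;O_2s:0.1329
v7	-26.89	C_2p:0.3087;C_2s:0.4984;H_1s:0.1929;N_2p:0.3473;N_2s:0.3738;O_2p:0.1543;O_2s:0.1246
v8	-25.19	C_2p:0.3290;C_2s:0.4653;H_1s:0.2056;N_2p:0.3701;N_2s:0.3490;O_2p:0.1645;O_2s:0.1163
v9	-23.52	C_2p:0.3492;C_2s:0.4326;H_1s:0.2182;N_2p:0.3928;N_2s:0.3244;O_2p:0.1746;O_2s:0.1081
v10	-21.91	C_2p:0.3692;C_2s:0.4001;H_1s:0.2307;N_2p:0.4153;N_2s:0.3001;O_2p:0.1846;O_2s:0.1000
v11	-20.34	C_2p:0.3888;C_2s:0.3682;H_1s:0.2430;N_2p:0.4374;N_2s:0.2761;O_2p:0.1944;O_2s:0.0920
v12	-18.83	C_2p:0.4082;C_2s:0.3368;H_1s:0.2551;N_2p:0.4592;N_2s:0.2526;O_2p:0.2041;O_2s:0.0842
v13	-17.37	C_2p:0.4271;C_2s:0.3060;H_1s:0.2669;N_2p:0.4804;N_2s:0.2295;O_2p:0.2135;O_2s:0.0765
v14	-15.98	C_2p:0.4454;C_2s:0.2762;H_1s:0.2784;N_2p:0.5011;N_2s:0.2071;O_2p:0.2227;O_2s:0.0690
v15	-14.66	C_2p:0.4632;C_2s:0.2473;H_1s:0.2895;N_2p:0.5211;N_2s:0.1855;O_2p:0.2316;O_2s:0.0618
v16	-13.41	C_2p:0.4802;C_2s:0.2197;H_1s:0.3001;N_2p:0.5402;N_2s:0.1647;O_2p:0.2401;O_2s:0.0549
v17	-12.25	C_2p:0.4963;C_2s:0.1935;H_1s:0.3102;N_2p:0.5583;N_2s:0.1452;O_2p:0.2481;O_2s:0.0484
v18	-11.18	C_2p:0.5112;C_2s:0.1693;H_1s:0.3195;N_2p:0.5751;N_2s:0.1270;O_2p:0.2556;O_2s:0.0423
v19	-10.24	C_2p:0.5246;C_2s:0.1475;H_1s:0.3279;N_2p:0.5902;N_2s:0.1107;O_2p:0.2623;O_2s:0.0369
v20	-9.45	C_2p:0.5359;C_2s:0.1292;H_1s:0.3349;N_2p:0.6029;N_2s:0.0969;O_2p:0.2679;O_2s:0.0323
v21	-8.94	C_2p:0.5432;C_2s:0.1173;H_1s:0.3395;N_2p:0.6111;N_2s:0.0880;O_2p:0.2716;O_2s:0.0293
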