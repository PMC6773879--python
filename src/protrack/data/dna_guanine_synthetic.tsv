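# SYNTHETIC per-MO table for guanine (Z=78, 39 MOs).
# Stand-in for an unpublished RHF/3-21G + Mulliken analysis; preserves MO count,
# electron count, atomic composition and the experimental Koopmans HOMO energy.
o_1s_core	-540.00	O_1s:2.0000
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
v1	-38.00	C_2p:0.1696;C_2s:0.6470;H_1s:0.0848;N_2p:0.2543;N_2s:0.6470;O_2p:0.0678;O_2s:0.1294
v2	-36.52	C_2p:0.1838;C_2s:0.6250;H_1s:0.0919;N_2p:0.2757;N_2s:0.6250;O_2p:0.0735;O_2s:0.1250
v3	-35.06	C_2p:0.1981;C_2s:0.6029;H_1s:0.0991;N_2p:0.2972;N_2s:0.6029;O_2p:0.0793;O_2s:0.1206
v4	-33.62	C_2p:0.2125;C_2s:0.5807;H_1s:0.1062;N_2p:0.3187;N_2s:0.5807;O_2p:0.0850;O_2s:0.1161
v5	-32.21	C_2p:0.2269;C_2s:0.5584;H_1s:0.1135;N_2p:0.3404;N_2s:0.5584;O_2p:0.0908;O_2s:0.1117
v6	-30.81	C_2p:0.2413;C_2s:0.5361;H_1s:0.1207;N_2p:0.3620;N_2s:0.5361;O_2p:0.0965;O_2s:0.1072
v7	-29.44	C_2p:0.2558;C_2s:0.5137;H_1s:0.1279;N_2p:0.3837;N_2s:0.5137;O_2p:0.1023;O_2s:0.1027
v8	-28.09	C_2p:0.2703;C_2s:0.4914;H_1s:0.1351;N_2p:0.4054;N_2s:0.4914;O_2p:0.1081;O_2s:0.0983
v9	-26.76	C_2p:0.2847;C_2s:0.4690;H_1s:0.1424;N_2p:0.4271;N_2s:0.4690;O_2p:0.1139;O_2s:0.0938
v10	-25.46	C_2p:0.2992;C_2s:0.4467;H_1s:0.1496;N_2p:0.4488;N_2s:0.4467;O_2p:0.1197;O_2s:0.0893
v11	-24.18	C_2p:0.3136;C_2s:0.4245;H_1s:0.1568;N_2p:0.4704;N_2s:0.4245;O_2p:0.1254;O_2s:0.0849
v12	-22.92	C_2p:0.3279;C_2s:0.4023;H_1s:0.1640;N_2p:0.4919;N_2s:0.4023;O_2p:0.1312;O_2s:0.0805
v13	-21.70	C_2p:0.3422;C_2s:0.3803;H_1s:0.1711;N_2p:0.5133;N_2s:0.3803;O_2p:0.1369;O_2s:0.0761
v14	-20.50	C_2p:0.3563;C_2s:0.3584;H_1s:0.1782;N_2p:0.5345;N_2s:0.3584;O_2p:0.1425;O_2s:0.0717
v15	-19.33	C_2p:0.3704;C_2s:0.3367;H_1s:0.1852;N_2p:0.5555;N_2s:0.3367;O_2p:0.1481;O_2s:0.0673
v16	-18.20	C_2p:0.3842;C_2s:0.3153;H_1s:0.1921;N_2p:0.5763;N_2s:0.3153;O_2p:0.1537;O_2s:0.0631
v17	-17.09	C_2p:0.3979;C_2s:0.2942;H_1s:0.1989;N_2p:0.5968;N_2s:0.2942;O_2p:0.1592;O_2s:0.0588
v18	-16.03	C_2p:0.4113;C_2s:0.2734;H_1s:0.2057;N_2p:0.6170;N_2s:0.2734;O_2p:0.1645;O_2s:0.0547
v19	-14.99	C_2p:0.4245;C_2s:0.2531;H_1s:0.2122;N_2p:0.6367;N_2s:0.2531;O_2p:0.1698;O_2s:0.0506
v20	-14.00	C_2p:0.4373;C_2s:0.2332;H_1s:0.2187;N_2p:0.6560;N_2s:0.2332;O_2p:0.1749;O_2s:0.0466
v21	-13.05	C_2p:0.4498;C_2s:0.2140;H_1s:0.2249;N_2p:0.6747;N_2s:0.2140;O_2p:0.1799;O_2s:0.0428
v22	-12.15	C_2p:0.4618;C_2s:0.1954;H_1s:0.2309;N_2p:0.6927;N_2s:0.1954;O_2p:0.1847;O_2s:0.0391
v23	-11.29	C_2p:0.4733;C_2s:0.1777;H_1s:0.2366;N_2p:0.7099;N_2s:0.1777;O_2p:0.1893;O_2s:0.0355
v24	-10.50	C_2p:0.4841;C_2s:0.1610;H_1s:0.2420;N_2p:0.7261;N_2s:0.1610;O_2p:0.1936;O_2s:0.0322
v25	-9.77	C_2p:0.4941;C_2s:0.1455;H_1s:0.2470;N_2p:0.7411;N_2s:0.1455;O_2p:0.1976;O_2s:0.0291
v26	-9.13	C_2p:0.5030;C_2s:0.1317;H_1s:0.2515;N_2p:0.7546;N_2s:0.1317;O_2p:0.2012;O_2s:0.0263
v27	-8.59	C_2p:0.5106;C_2s:0.1200;H_1s:0.2553;N_2p:0.7659;N_2s:0.1200;O_2p:0.2042;O_2s:0.0240
v28	-8.24	C_2p:0.5155;C_2s:0.1124;H_1s:0.2577;N_2p:0.7732;N_2s:0.1124;O_2p:0.2062;O_2s:0.0225
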