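# SYNTHETIC per-MO table for sugar_phosphate (Z=96, 48 MOs).
# Stand-in for an unpublished RHF/3-21G + Mulliken analysis; preserves MO count,
# electron count, atomic composition and the experimental Koopmans HOMO energy.
p_1s_core	-2150.00	P_1s:2.0000
o_1s_core	-540.00	O_1s:2.0000
o_1s_core	-540.00	O_1s:2.0000
o_1s_core	-540.00	O_1s:2.0000
o_1s_core	-540.00	O_1s:2.0000
o_1s_core	-540.00	O_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
c_1s_core	-305.00	C_1s:2.0000
p_2s_core	-200.00	P_2s:2.0000
p_2p_core	-145.00	P_2p:2.0000
p_2p_core	-145.00	P_2p:2.0000
p_2p_core	-145.00	P_2p:2.0000
v1	-38.00	C_2p:0.1604;C_2s:0.5883;H_1s:0.1764;O_2p:0.3208;O_2s:0.5883;P_3p:0.0481;P_3s:0.1177
v2	-36.85	C_2p:0.1707;C_2s:0.5678;H_1s:0.1877;O_2p:0.3413;O_2s:0.5678;P_3p:0.0512;P_3s:0.1136
v3	-35.71	C_2p:0.1808;C_2s:0.5474;H_1s:0.1989;O_2p:0.3617;O_2s:0.5474;P_3p:0.0543;P_3s:0.1095
v4	-34.58	C_2p:0.1909;C_2s:0.5273;H_1s:0.2100;O_2p:0.3818;O_2s:0.5273;P_3p:0.0573;P_3s:0.1055
v5	-33.47	C_2p:0.2009;C_2s:0.5073;H_1s:0.2210;O_2p:0.4018;O_2s:0.5073;P_3p:0.0603;P_3s:0.1015
v6	-32.37	C_2p:0.2108;C_2s:0.4875;H_1s:0.2319;O_2p:0.4216;O_2s:0.4875;P_3p:0.0632;P_3s:0.0975
v7	-31.28	C_2p:0.2206;C_2s:0.4680;H_1s:0.2426;O_2p:0.4411;O_2s:0.4680;P_3p:0.0662;P_3s:0.0936
v8	-30.21	C_2p:0.2302;C_2s:0.4486;H_1s:0.2532;O_2p:0.4604;O_2s:0.4486;P_3p:0.0691;P_3s:0.0897
v9	-29.15	C_2p:0.2398;C_2s:0.4296;H_1s:0.2637;O_2p:0.4795;O_2s:0.4296;P_3p:0.0719;P_3s:0.0859
v10	-28.11	C_2p:0.2492;C_2s:0.4107;H_1s:0.2741;O_2p:0.4984;O_2s:0.4107;P_3p:0.0748;P_3s:0.0821
v11	-27.09	C_2p:0.2585;C_2s:0.3921;H_1s:0.2843;O_2p:0.5170;O_2s:0.3921;P_3p:0.0775;P_3s:0.0784
v12	-26.08	C_2p:0.2677;C_2s:0.3738;H_1s:0.2944;O_2p:0.5353;O_2s:0.3738;P_3p:0.0803;P_3s:0.0748
v13	-25.09	C_2p:0.2767;C_2s:0.3557;H_1s:0.3044;O_2p:0.5534;O_2s:0.3557;P_3p:0.0830;P_3s:0.0711
v14	-24.11	C_2p:0.2856;C_2s:0.3379;H_1s:0.3142;O_2p:0.5712;O_2s:0.3379;P_3p:0.0857;P_3s:0.0676
v15	-23.15	C_2p:0.2944;C_2s:0.3204;H_1s:0.3238;O_2p:0.5887;O_2s:0.3204;P_3p:0.0883;P_3s:0.0641
v16	-22.21	C_2p:0.3030;C_2s:0.3032;H_1s:0.3333;O_2p:0.6059;O_2s:0.3032;P_3p:0.0909;P_3s:0.0606
v17	-21.29	C_2p:0.3114;C_2s:0.2863;H_1s:0.3425;O_2p:0.6228;O_2s:0.2863;P_3p:0.0934;P_3s:0.0573
v18	-20.39	C_2p:0.3197;C_2s:0.2698;H_1s:0.3516;O_2p:0.6393;O_2s:0.2698;P_3p:0.0959;P_3s:0.0540
v19	-19.52	C_2p:0.3278;C_2s:0.2536;H_1s:0.3605;O_2p:0.6555;O_2s:0.2536;P_3p:0.0983;P_3s:0.0507
v20	-18.66	C_2p:0.3357;C_2s:0.2378;H_1s:0.3692;O_2p:0.6713;O_2s:0.2378;P_3p:0.1007;P_3s:0.0476
v21	-17.82	C_2p:0.3434;C_2s:0.2224;H_1s:0.3777;O_2p:0.6867;O_2s:0.2224;P_3p:0.1030;P_3s:0.0445
v22	-17.01	C_2p:0.3509;C_2s:0.2074;H_1s:0.3859;O_2p:0.7017;O_2s:0.2074;P_3p:0.1053;P_3s:0.0415
v23	-16.23	C_2p:0.3581;C_2s:0.1928;H_1s:0.3939;O_2p:0.7163;O_2s:0.1928;P_3p:0.1074;P_3s:0.0386
v24	-15.47	C_2p:0.3652;C_2s:0.1788;H_1s:0.4017;O_2p:0.7303;O_2s:0.1788;P_3p:0.1095;P_3s:0.0358
v25	-14.74	C_2p:0.3719;C_2s:0.1652;H_1s:0.4091;O_2p:0.7439;O_2s:0.1652;P_3p:0.1116;P_3s:0.0330
v26	-14.04	C_2p:0.3784;C_2s:0.1522;H_1s:0.4163;O_2p:0.7569;O_2s:0.1522;P_3p:0.1135;P_3s:0.0304
v27	-13.38	C_2p:0.3846;C_2s:0.1399;H_1s:0.4231;O_2p:0.7692;O_2s:0.1399;P_3p:0.1154;P_3s:0.0280
v28	-12.75	C_2p:0.3904;C_2s:0.1282;H_1s:0.4295;O_2p:0.7809;O_2s:0.1282;P_3p:0.1171;P_3s:0.0256
v29	-12.17	C_2p:0.3959;C_2s:0.1173;H_1s:0.4355;O_2p:0.7918;O_2s:0.1173;P_3p:0.1188;P_3s:0.0235
v30	-11.64	C_2p:0.4009;C_2s:0.1073;H_1s:0.4410;O_2p:0.8018;O_2s:0.1073;P_3p:0.1203;P_3s:0.0215
v31	-11.16	C_2p:0.4053;C_2s:0.0984;H_1s:0.4459;O_2p:0.8107;O_2s:0.0984;P_3p:0.1216;P_3s:0.0197
v32	-10.77	C_2p:0.4090;C_2s:0.0910;H_1s:0.4499;O_2p:0.8181;O_2s:0.0910;P_3p:0.1227;P_3s:0.0182
v33	-10.51	C_2p:0.4114;C_2s:0.0862;H_1s:0.4526;O_2p:0.8228;O_2s:0.0862;P_3p:0.1234;P_3s:0.0172
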