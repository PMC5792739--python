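gene	hr_a	ci_low_a	ci_high_a	p_a	fdr_a	hr_b	ci_low_b	ci_high_b	p_b	fdr_b
CD82	0.58415	0.48411	0.70485	2.03E-08	0.00020	0.52520	0.37432	0.73692	0.00019	0.00153
LFNG	0.60248	0.45858	0.79153	0.00027	0.01102	0.52328	0.38240	0.71605	5.18E-05	0.00055
PTK2B	0.64250	0.52325	0.78893	2.41E-05	0.00364	0.47279	0.31916	0.70039	0.00019	0.00148
CCL5	0.67761	0.56575	0.81157	2.35E-05	0.00360	0.57686	0.41392	0.80393	0.00116	0.00629
LSP1	0.68714	0.57354	0.82325	4.71E-05	0.00497	0.48760	0.33130	0.71764	0.00027	0.00201
DDX60	0.71537	0.59150	0.86520	0.00056	0.01594	0.53727	0.34560	0.83524	0.00578	0.02156
PARP14	0.71561	0.58722	0.87208	0.00091	0.02035	0.57359	0.37679	0.87319	0.00953	0.03145
TUBA4A	0.71722	0.60117	0.85567	0.00022	0.01002	0.31663	0.23623	0.42440	1.42E-14	4.79E-12
GPX3	0.71882	0.60071	0.86016	0.00031	0.01170	0.26009	0.10878	0.62186	0.00246	0.01130
NDUFA4L2	0.72297	0.60147	0.86901	0.00055	0.01588	0.67309	0.50482	0.89746	0.00700	0.02488
GABRE	0.72349	0.59532	0.87925	0.00114	0.02295	0.42004	0.28150	0.62674	2.16E-05	0.00028
BTBD6	0.72365	0.58391	0.89682	0.00313	0.04005	0.47218	0.25171	0.88574	0.01938	0.05445
ITM2A	0.72406	0.60252	0.87011	0.00057	0.01613	0.35698	0.25098	0.50776	1.00E-08	3.96E-07
HDC	0.73176	0.61012	0.87764	0.00076	0.01881	0.63449	0.51806	0.77708	1.09E-05	0.00016
ELF4	0.73257	0.61273	0.87584	0.00064	0.01716	0.56910	0.38619	0.83865	0.00438	0.01738
RIPK3	0.73743	0.62606	0.86861	0.00027	0.01085	0.40256	0.30353	0.53388	2.67E-10	1.57E-08
CCBE1	0.73817	0.59969	0.90862	0.00418	0.04704	0.35930	0.14251	0.90584	0.03004	0.07619
PON3	0.74237	0.61458	0.89673	0.00200	0.03083	0.64187	0.53994	0.76304	5.02E-07	1.23E-05
BOC	0.74269	0.61053	0.90345	0.00292	0.03872	0.67546	0.50016	0.91219	0.01048	0.03398
RUNX1T1	0.74951	0.61916	0.90730	0.00310	0.03987	0.57779	0.40754	0.81917	0.00207	0.00983
FILIP1L	0.76881	0.64177	0.92100	0.00433	0.04808	0.49836	0.36807	0.67478	6.67E-06	0.00011
NDRG2	0.77243	0.64328	0.92751	0.00567	0.05603	0.56030	0.40811	0.76923	0.00034	0.00241
TSPAN33	0.77331	0.65148	0.91792	0.00329	0.04124	0.46715	0.24663	0.88486	0.01953	0.05474
FAM110C	0.77589	0.64552	0.93259	0.00686	0.06188	0.62169	0.44282	0.87281	0.00603	0.02221
JUP	0.77882	0.65184	0.93053	0.00591	0.05722	0.61515	0.51528	0.73437	7.62E-08	2.36E-06
RUNX3	0.78039	0.64937	0.93784	0.00818	0.06857	0.34593	0.21468	0.55742	1.29E-05	0.00018
EGLN3	0.78592	0.64904	0.95166	0.01361	0.09212	0.42935	0.31385	0.58735	1.23E-07	3.61E-06
MID1	1.37339	1.09496	1.72262	0.00606	0.05803	3.45380	2.09940	5.68197	1.06E-06	2.28E-05
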