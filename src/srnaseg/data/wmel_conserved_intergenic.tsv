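start	end	upstream	downstream
44380	44468	dnaJ	tRNA-Arg-1
85867	85929	dprA	WD0093
279526	279619	WD0299	coxB
547479	547732	nuoD	WD0562
611202	611370	WD0625	WD0626
612281	612391	WD0626	WD0627
622779	622923	WD0632	WD0633
623094	623293	WD0632	WD0633
639293	639403	fabG	WD0651
719048	719171	WD0744	WD0745
723861	724026	WD0749	WD0750
764459	764871	WD0790	WD0791
768936	768988	rho	WD0796
850067	850142	WD0878	trx
932596	932693	WD0973	WD0974
940039	940142	nuoI	trmE
941823	941975	tRNA-Ser-2	WD0982
1039579	1039870	WD1081	WD1082
1105661	1105744	tRNA-Thr-2	mutM
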