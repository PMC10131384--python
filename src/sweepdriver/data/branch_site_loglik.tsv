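# Branch-site model log-likelihood pairs for eight cancer driver genes with
# evidence of positive selection on the human lineage (alternative model A
# vs null model B with omega2 fixed at 1); omega is the foreground
# site-class dN/dS estimate from the alternative fit, passed through.
gene	branch	lnl_alt	lnl_null	omega
DROSHA	human	-9569.2	-9593.43	202.65
LY75-CD302	human	-15467	-15535	200
RBFOX1	human	-2118.24	-2147.37	270.69
NRG1	human	-5366.86	-5379.37	94.63
STAT3	human	-5563.45	-5577.78	92.15
NIN	human	-17468.17	-17477.49	791.16
ZNF814	human	-4723.37	-4734.49	5.37
TRAF3	human	-4022.31	-4033.59	999
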