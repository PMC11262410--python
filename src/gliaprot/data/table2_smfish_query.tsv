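gene_symbol	fbgn_id	predicted
Lac	FBgn0010238	Yes
Pdi	FBgn0286818	Yes
nrv2	FBgn0015777	Yes
Lost	FBgn0263594	No
Flo-2	FBgn0264078	Yes
alpha-Cat	FBgn0010215	Yes
Vha55	FBgn0005671	Yes
Atpalpha	FBgn0002921	Yes
Nrg	FBgn0264975	Yes
Cip4	FBgn0035533	Yes
Nrx-IV	FBgn0013997	No
gs2	FBgn0001145	Yes
shot	FBgn0013733	Yes
kst	FBgn0004167	No
sdk	FBgn0021764	No
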