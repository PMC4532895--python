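# SYNTHETIC coefficients: per-site-type OLS fit of the 14 model features
# on a simulated single-site training compendium (see scripts/make_shipped_model.py).
# These are stand-ins for a published coefficient release, not estimates from
# experimental data.
site_type	term	value
6mer	intercept	-0.015761811340230913
6mer	cap	0.0
6mer	TA_3UTR	0.06254036074898273
6mer	SPS	0.019447825095629968
6mer	Local_AU	0.03411312212887242
6mer	3P_score	0.009714491167017987
6mer	SA	0.009405505323721464
6mer	Min_dist	-0.040031272212061056
6mer	P_CT	-0.017991916263382042
6mer	Len_ORF	0.0
6mer	Len_3UTR	0.08858544105986195
6mer	Off6m	0.006646225492315565
6mer	ORF8m	-0.004657582856216995
6mer	sRNA1_A	0.009436441044120813
6mer	sRNA1_C	0.013533689263527212
6mer	sRNA1_G	-0.0011944259650464501
6mer	sRNA8_A	-0.003954850681667011
6mer	sRNA8_C	0.021848809756781853
6mer	sRNA8_G	-0.005980962052215834
6mer	site8_A	0.0116349662102815
6mer	site8_C	0.017174278853027275
6mer	site8_G	0.021273879446597106
7mer-A1	intercept	0.02199540913240077
7mer-A1	cap	-0.01
7mer-A1	TA_3UTR	0.20171758187418523
7mer-A1	SPS	0.014882543813804987
7mer-A1	Local_AU	0.02751710946804839
7mer-A1	3P_score	-0.0025356022195754495
7mer-A1	SA	-0.08623879235043103
7mer-A1	Min_dist	0.026995495553281613
7mer-A1	P_CT	-0.022035203939401213
7mer-A1	Len_ORF	0.0
7mer-A1	Len_3UTR	0.02981154937559525
7mer-A1	Off6m	0.009345456330527526
7mer-A1	ORF8m	-0.01269544258344224
7mer-A1	sRNA1_A	-0.012595563049486808
7mer-A1	sRNA1_C	-0.00024009385563250867
7mer-A1	sRNA1_G	-0.009629094999769473
7mer-A1	sRNA8_A	-0.032458746461518695
7mer-A1	sRNA8_C	-0.005407255934221958
7mer-A1	sRNA8_G	-0.004647919759241571
7mer-A1	site8_A	0.004027200064109915
7mer-A1	site8_C	0.005501449709361029
7mer-A1	site8_G	-0.045406655525036047
7mer-m8	intercept	-0.31404262663835764
7mer-m8	cap	-0.02
7mer-m8	TA_3UTR	0.03677750507737938
7mer-m8	SPS	0.02953908596125937
7mer-m8	Local_AU	-0.021906312590653107
7mer-m8	3P_score	-0.0345993465140163
7mer-m8	SA	-0.15165472306690098
7mer-m8	Min_dist	-0.01574557227677392
7mer-m8	P_CT	-0.02814778160121336
7mer-m8	Len_ORF	0.0
7mer-m8	Len_3UTR	0.0918497990263238
7mer-m8	Off6m	-0.002393064064733371
7mer-m8	ORF8m	-0.0020143177036652826
7mer-m8	sRNA1_A	-0.007283067937539733
7mer-m8	sRNA1_C	0.009091720302513083
7mer-m8	sRNA1_G	0.038971548074878924
7mer-m8	sRNA8_A	0.010902372882816442
7mer-m8	sRNA8_C	0.021761486906873462
7mer-m8	sRNA8_G	0.04805395104857002
7mer-m8	site8_A	0.0
7mer-m8	site8_C	0.0
7mer-m8	site8_G	0.0
8mer	intercept	-0.42587478727859013
8mer	cap	-0.03
8mer	TA_3UTR	-0.07524376938064925
8mer	SPS	0.04975657864340188
8mer	Local_AU	-0.05002508681947312
8mer	3P_score	-0.05310225413740062
8mer	SA	-0.060552929029739626
8mer	Min_dist	0.07560296671658465
8mer	P_CT	-0.06724997869548613
8mer	Len_ORF	0.0
8mer	Len_3UTR	0.04590409717924004
8mer	Off6m	-0.006226109449900194
8mer	ORF8m	0.00043808386715759283
8mer	sRNA1_A	0.004536621858932494
8mer	sRNA1_C	0.017322679536951047
8mer	sRNA1_G	-0.043199616589734174
8mer	sRNA8_A	-0.01866478030542916
8mer	sRNA8_C	0.003500828250516029
8mer	sRNA8_G	0.013079010493371734
8mer	site8_A	0.0
8mer	site8_C	0.0
8mer	site8_G	0.0
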