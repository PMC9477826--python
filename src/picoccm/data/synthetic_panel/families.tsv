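family_id	category	search_mode	min_query_coverage	min_identity	length
rbcL_1A	rubisco	score	75.0	30.0	227
rbcL_1B	rubisco	score	75.0	30.0	266
rbcS	rubisco	score	75.0	30.0	278
cbbX	activase_chaperone	score	75.0	30.0	230
rbcX	activase_chaperone	score	75.0	30.0	197
raf1	activase_chaperone	score	75.0	30.0	215
raf2	activase_chaperone	score	75.0	30.0	231
cmpR	regulator	score	75.0	30.0	230
cyaAbr2	regulator	score	75.0	30.0	163
csoS1	carboxysome	score	75.0	30.0	176
csoS2	carboxysome	score	75.0	30.0	239
csoS4A	carboxysome	score	75.0	30.0	255
csoS4B	carboxysome	score	75.0	30.0	182
ccmK	carboxysome	score	75.0	30.0	288
ccmL	carboxysome	score	75.0	30.0	236
ccmM	carboxysome	score	75.0	30.0	272
ccmN	carboxysome	score	75.0	30.0	243
ccmO	carboxysome	score	75.0	30.0	187
ccmP	carboxysome	score	75.0	30.0	170
ca_alpha	carbonic_anhydrase	profile	75.0	30.0	162
ca_beta_A	carbonic_anhydrase	profile	75.0	30.0	255
ca_beta_B	carbonic_anhydrase	profile	75.0	30.0	282
ca_beta_C	carbonic_anhydrase	profile	75.0	30.0	218
ca_beta_D	carbonic_anhydrase	profile	75.0	30.0	294
ca_gamma	carbonic_anhydrase	profile	75.0	30.0	256
ca_epsilon	carbonic_anhydrase	profile	75.0	30.0	176
cmpA	ci_transporter	profile	75.0	30.0	162
cmpB	ci_transporter	profile	75.0	30.0	233
cmpC	ci_transporter	profile	75.0	30.0	223
cmpD	ci_transporter	profile	75.0	30.0	289
bicA	ci_transporter	profile	75.0	30.0	166
sbtA1	ci_transporter	profile	75.0	30.0	194
sbtA2	ci_transporter	profile	75.0	30.0	175
ictB	ci_transporter	profile	75.0	30.0	188
chpX	ci_transporter	profile	75.0	30.0	175
chpY	ci_transporter	profile	75.0	30.0	264
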