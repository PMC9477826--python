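>ca_beta_D|aln1
MDSEAWLSMDCGSFKFFRPRIGGNVVHRSTKGYLISAVASEMGWRFCQRTFGDLDWWPFTCVCKRYMNVPCIYWWPDQLGSRHIGISVHNIAAMGGPTTEMGMVYLQDWAEPAGSFVKRFMVCTGDQHVWGCTFYAAAICCPVMMDPCYMGWYERMTSMRYNWFARASVRICQCQPEDHSFMYLLVDYMRCNIEKKIRQKHHVSSNGVTVYHTEAEKFIVNGMCPPCWSPIFTCKYEHELNILIAQMWRNTRFSMCLGHLNFTDPIINALKFGMHCWARPIRDRVEHKENPENE
>ca_beta_D|aln2
MDSEAWLSMDCGSFKFFRRRIGGNVVHRSTKGYLISRVMSEMGWRLCQRTFGKLWLWPFTCVCKYYMRVPCKYWWPDQLGNRHIKISDHNMACMGGPTAHMGMVVLQDWAEPAGSFVKGFSYCTGDQDVWGTTFYYAAMTCPWMMDPCYMGWYEVMTSGRYNWFAFASVRICDCQPEDHSGMGLLVDYMRCNIEKKIRQKHHDSSQGVSVYHTEAEKHIVNGMCPPCWSPIFTCKYEHEKNILIAQRWRNTRFSMRLGHLNFTDGIINALHFGMHCWGRPIRDRVLHKENPENE
>ca_beta_D|aln3
MDSEALKSVWCGSFEFFRPRIGGNAVHCSTWGYLKSAVASEMGWGICVRTFGELDQWPFTCVCKRYMNVKCWYWWPYQLGSRMIGISVHNIAYVGGPTTEIGMVYLPDCAENAGSFVERFSVCTGCQHVWGCTFAAKAICGPVMMDPCYMGIYERVTSMRVNHFARATVRFCQQGPEDHSGMYLLVDYMICNIEKKIRQKEHVSSNHVTVYHTHREKFLLNGMCPPCWKPIFWCKYHHELNILIAQMWRETRFSLCLGHLNATDTIINKLRFGMHCWAHPINDRVMHKENGENE
>ca_beta_D|aln4
MDSEAWLSMDAKSFKHFRPIINGNNVHESTDGCFISLALSIMVWRFCQRTFGDCDWRPCTCVVYRYGNVPCIYWWPDQLGSRHIGISVPNIAAMVSVTMEWGMVALQHWAEPAGQFVKIFMVCTPEQHVWNGTFYAAAICHPVMMDFCYMHWYDRKTSHRYAGFARARTRICRCQPEDHSFMSFLVDYHRCEIEWKIRQNKYVSSNGVCVYAGMHEKIISNGMCPACWSGGFTCKYEHELNILIMQLPRNTCESMCLGHLNFADPIINALKFGKHIWERPIRDRVEHKENPENK
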