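>ca_beta_C|aln1
MCGITHKRKGNFWKIEGAQFPPLPQPDPKRWAMESIVLDVPEYPSDGRPSCILTPCFDQLSSGEMYPHMNYFMSNVGYHNISMQFVWLMKWEISTKMWKCSGSLETRQENGALVDTDSEGIIITPYWPAFQCQYAWAVDEMGRWNIKDVYYEARGTVPHVQRMITDCHPNIHTDDITMRLLKKSWGTNKNMYWCDDPGVADKSSLSPIVWELFPIYGM
>ca_beta_C|aln2
MCDITRKRTGNFWKQEGAQFPPLPQPDPKRLAMESIVQDVPEYPSDIHPSCILTPCFDQLSSGEMYPHMNYFMDNVGYHNIYMWFVPLMKWEISTKMWKCSGSLETGWENGALVDTDSEGIIKTPYWFAFFCQYAWACDWMGRWNILDVYYEARGTVPHHQRMITDCHYNIHTDDHTMALPYGSWRTNKNMYWCDDAGVGDLSSLSPKVWCLFPIYGM
>ca_beta_C|aln3
MCGITHKRKGNFWKIEGASFPPLPQKRPKRWAQESIVLDVPWYARDGRPSCDLTPHFVRLSSIEMEPHGNGFMSNVGYHGIDPQFVWLMKWEISTIMWKCSGTLEFRYPNGALVDTKSERWIITWYWPALHFQYVWAVDEMGRWNIKDVYYEAATTVPHVQRMITDCHPNIHTILITMRALKKSWGTNKNMEWCMDPGLADKQSLSFIVWELQTIYGK
>ca_beta_C|aln4
MCFITHKRVGNFWKIEGAQFPPLPQPDPKRWLMTHIVLDNPTYQSDGRPSTILQHCFMQESSGEIYPHMVYFMSNPGYEFCSMQFVWLMPEEVYTKMWYTGGKLEHRQENGAIVDTDSEGIIPTPYHPAFQVSYAWAVDKMGVHNTKDVYYEARYTVPHGQLMITDCMPNSHTDDITMRLLKKSWGTNILDYNCNDLGVADVMLLSPIGWELFPIIGF
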