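>cmpD|aln1
MDSDIPPFWRQQLMAKEHNDHVDYNHCFEEHFDGTNTFQSHWSGNTNIGMANDWWRASRQERVTLWMNVDEYMAVRPTKRVHIWCVKTPPAPWREHYCYEIIRDPAVFCIYDAWQTMMTHNWDFACMIPWTHDNISVFEHMWDCLQEHMLASDNGQKVVTEGQFHKPICNHLTHWHRALGHTLECGVDTPYILLHLKCRSMACHLRDMRNTWIWESRRDELHRNFCFLECTTLIGAPMQQKWTNTQYTCAGNHQYTPKCTMHNPIVLYMRPHVIYICLGINPMLYVDNI
>cmpD|aln2
MDNDIPPFWRCQGKAKYHNDHVDYNHCHEENFDGTNTFQSHPSGNRNIGPANDWWRASRQERVALWMNNDEYPAVRPTKRVHRWAVKTPPAPWREHYCYEIIRDPAVFCIYDAWQTMMTVNWDFACMIPWTHDNISVFEHMTDCLQEQMMASDNGQKVVTEGNEHDPPCNHLTHWHRALLHRLQQGVDTPYDLLHLKCESMAPHLRDMRNTWESESRDDRLHRNDCFLECTTLIGAPMQQKWTNTQMTCAGDHQYTPKYTTHNPIELYMFPHVLYICLGINVMLYVDNI
>cmpD|aln3
MDLDVPTTWRQQLMAWEHNDKVDYNHDFEEHPVGTNLFWSHWSGNTNILMANDWWRALRQERVTLWMNVDEYMAVDPTKRVHIWCVKTPPLPWREHYAYYIPRYPAVFCIYNAWQTMMQHNWHFACPIPWTHDNISFFEHMFDCLQEHMLASDNGQKVETIGQFHKPICEHLIHWERASGHTLECGVNTPLSLLMLKQRRTACHRDDQRNTWEMESRQDELDRNFCFLACTTLIGYMMQQKWTNTFYTCAPLHQYTPCCTTHNPIVLYDRPTQIYICLGCNPMLYVDQI
>cmpD|aln4
MDSDTPPFWRQQLMAKEHGDHVDYHHMFEKHFDGTKTFQSHHSGPWNIGMANDFWHAVRQEEVTLWMNEDEYMAVRPTKRVHITQVKRPTAPWRELKCYQILMDPARFCRYDANQTMGTHNVDLDCMEPWTNDNIRVIEPMWDCLQEHMLASDNGQKVVREGCFKGTNCNHLTAGHMALGHTLECGVDTPYIELHLKCRSMACHYRDNRNTWFWESRRQELHANFCTLEAETLIGTPGQMRQPNNQDTCAGNHVMGWKCTMVNPIVLYMRPQSEYICLGANPMLYTDNG
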