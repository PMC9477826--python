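>chpY|aln1
MGTKQTLIWEPLGWYEEWNAQPHPCTKACFYARCNKRIYHVHMSQIYAEILYCCKYFTENDPQTKMKVGNNESMYLKQSEWWGTGVHIWVNMESWVHQMWHCNHAETTGSISFTETWCGANDYIERPNFPLEEISPFNTGQWPMVKWPESVVMYPIEQDNLVRTYVEDVYPWYDFFYPQINFSGMPDIMEHEPWMPFWDMKAWETGCRLDSCPDPADLDHDWEDFYGLDPAEAAVACFCEYFYAISNDVSYVWPPAVGDSMKGQ
>chpY|aln2
MGTKQTLIWEPYGWYEWDNAQPHPCTKTCFYAFCNKRSYHVHMSQIYAEILYCCKYCTENDPQTKMEVGNNESMYLKKSEWDGTGVHIWVNMGFWVHQMWHCNHSETEASISFTETWHGANAGIARPNIPLEEISPFNTGQWPMVKWPISWKMIPILQDNLVRTKVEKVRPWYDFFLPQINFSGMPDIMEHEPWMPFWDMCAWSTGHLLASCPDPCDLLQWWEDFYGLDPANAAVACFEEYFYAISNDVSYVWPPAVGDSMKGQ
>chpY|aln3
MGTKQTLIWEPLGWYEEWNADVKPMTKQCFYARCNKRCYHVRMSQIYAEGLYCCKYFTHNKLQTKDKGGNEPSNYLKQSEIWGFVVHIWVNMESAVHQMTHCNQAEPTSSQSFTETWPGANDSIERPNFDQEVISPFNTGQWKMVKWPWNIVMYPKEQDFLYRTYIEDVYPWYDFFEPQINFSGQPDIMEHEPAMPFIDMKAWETGCRLDGCPNPADLDHDWEDSYVLNPAEAAVACFCEYFYATVSDASYVWPCAVGDSEKGQ
>chpY|aln4
MGTKGTLIWEMLGWYESWWAQEHPCTIACFYWRPNKRIYQVHMSVCPHTMLYGCRYFTENDPTLKMKVGDNESMYNKQSEWWPTGVGIWVNVEDHVHQMPKDFHAETRGSIIFTETWCIANDYHPHPNIPLAEVRDFNPGYWPMVKWPESVYMYPMEQYNLVRTYVEYRYPWYDFFYHPPNFSGMTDIIEHEPWMCTWDMEAWEDGCELDSKPDPAELDHDWEDQYPLDPAEAASACFGEYFYAISNDVSYVWPPAVGDSMHGC
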