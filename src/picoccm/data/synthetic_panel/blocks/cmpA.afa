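>cmpA|aln1
MLWMMGMEDDWPKIEISAATRKTHYPRPIQNDTKEKCTPWVHPLIPIKNMNKYLKRQWICFTGITRWSFLLSTPGPWDYEQCPRCQVFVDWPRMEHQIKMDVGDEWYRSWQELQCDFSFMTGPKFKEMTSCNEGSVTERNEKADKPFHRYHAWRNDYTISHM
>cmpA|aln2
MCWMMEMEKDWPKIEISAATRKLHMPHPIVNDTKEKCTPWVHPLIPITNMEKYLKRQWICMTGISRWSFLRSTPGPWDYETYPYCCVFVDWPRMEAQIKPDVGDCWYRDWQELQCDFFFMTGPKCKEMTRCNEGSVTERNEKYDKPFHRYHAWRNDYTISHM
>cmpA|aln3
MLCMMGMEYDWPKIEISAATTKTHYPRPIASDTKEKCTPWVISLYRISLMNKYLKRQWIRFTGCTRWTKLLSTPGPWDYEQCPRCQKFNDWPIMEPQITMDVGDEWYRSWQELQCDFSLMTGSKFIEMTSCNEASVCERCEKAPKPFNRYHLWRVDETISHT
>cmpA|aln4
MLWMMGMEDIWPKWIIVAATRKTHYPRGIQQKTKYKCTPNVHPCMPIKAMNKIEKRQWICVTGDVRWSRLLSTPGPWDYEQQPRTQCFSDWPRFEHQTKMDAGDNWYRVWHNLQCDFQHMTGPKDKEMDSFNEGSVTERNEMKDNPFHRDHAQPNDYTISHM
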