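>sbtA1|aln1
MNSWYCKEECQHMLDLVNDFPCFVIHTRGGDPDLPKYNVWWNEAFVLNCFEDVQDHPIENHAFTSYERWRARSMWDHCRCLHTKPRWNQWCGYKPTACFVYDRYVAEGAFAHIINLCEYEAVDVWRCIYTHVCDNNPGAWYCEGVQCTRNTDVLFFTFTACRMCGGLKDGGWCKSVFWDMYKWFTYKMNIWQCS
>sbtA1|aln2
MNDWYNKEECQHMLDLVNDFCCFVIHTRGGDPDLFKYNVWWNEAFVINPFDKVQDEPIENHPFTSYYRWRARSMWDWCTCLPTKPRWNQWCAYKPTACFAYDRRVIEGAFAHEKHLCETEAVDVWRCIYTHVCDNNPGAPYCVGVQCTTNTDVIFFTFTACPMCGGLKDGGWCKSVFWDMNKWFTYKMNIWQPS
>sbtA1|aln3
MNSWYCKQECQHMFDLVNTVPCFHIHTRYYDPDEPKYNEGWNEAFVLNCFEDVHDHPIEDEAFIGYERKVNRVYWDMCMCLHTHPRQNQCYVYKPTACFVYDRYVNEGAFAHIINLCEREAVDVWRCFSTHFCFNNPGAWYCEGVQCTPNTDVLFFTATACRMCNSLKDCAWCKSVFWDMYKWFTYKMNIWQCS
>sbtA1|aln4
MNSWYHKEVCAVMLDLVNDKPCKVIHTRGGFPDLPKPMVWWNEAFVLNCQKKEADHGAENHAFTLIERWRARSIWDHGRCLHTKAPWWWLDGYKVTECFVPDIYVAEAAFFHNINPCKYEAVDVWRCIYTHVCDNNPGAWYCEGVQQTRNTDFEPFTFMMCRMKGFLKWGCWCKSVFWDMYKYFTYKMDIQQCS
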