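>sbtA2|aln1
MYNMMCVKEWDKMEVDYHPDVTNLTHEFLIRDSWAALCFKYVKRAMTDDKAFSRLLCFGYFDNLIYFQIVIMLLRCIYNDMQGKWQPEAEPYQGFWHSLNEYRHKIQRICFDMGNHTHQVNSAPLLNHIGHRNLEIYLIPPTFCVTMCICVIRVIEKWEGWRIVPCKGVAKTHKE
>sbtA2|aln2
MYNLMCVKESDKMEVDYHPDVTNLTHEFLIRDSDAALCFKYVKRLMTDDKAFSRLLMFSYFDNLIYFQIGIMLLDCICNDMQGKWQPEAEPYKGFWHRLNEYRHEIQRFCEDMGNHSHQVWSQPLLNHIGHRNTEIYPISPTFCVTDCGCVIRVIEKWECGRIVPKKLVAKTHKE
>sbtA2|aln3
MYNMECVKEWDSMEVWYHPIVTNLTHEFVIRLSWAVLCFKYVKKAMTDDKAMSRLLCFGYWCNLIYFPIVIMLLRCIIDDMQGKWQPEAEPYQGFWHSLNEYRHKIQRICFDISNHTSQVNEAPWLNHIGHRNLEGFLFPPTFHVTMCICVTAVTEKWDGNRIRSAHGVVKTHNK
>sbtA2|aln4
MTNMMYSKEWDKMEVDQLPDVTNLTHEFLYRDSWAALCRKYFKTAWTDDKAHSRLLCFGYFDNLIYHQIVVMLLRKWYTDMQGKWEPEAEPYQDSWYSLCEYRHKWGRICFSMGNTTSQVNSALPLNYIGCRELLIYLCPTRFCVYMCICVIKVITKREGWRPFPEKGVAKDDKE
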