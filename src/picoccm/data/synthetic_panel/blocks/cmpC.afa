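>cmpC|aln1
MNHAQARPHLLIACMSYSQPGLTPHHNMRDSTAYVAEGIINLIDDGDINTHRQTSMACDPMTAMQGHMDRCHACGYYHAQSETLAPGTKYYLSGMCVHTRQWFVFSHLAWNMGKCHVFEHGCEKDFTDNLHCDPLAEDGFEYGLLIHQHQMDFKYNVWVMGLTNKWFCVSTPNDNKKQKFVVSQIPRADIHVQNHVLLNMIWLDMRNTVVMIQKLSWVSGDNM
>cmpC|aln2
MNHAQARPHLLIACMSYSQPGLTPHHNIRDSTAYVAEGIWNDVDDDQINTHRQTSMQCDTMTAMQGHMDRGHACGYYHAQSDSLAPGTKYYLRVMCVVTRQWTVFCHLHWNMGKCMVLEHGCEQDFMDKKHCDPDAEDGFEYGLLLHQHQMDCKYNVWVMGLFNKWFCVSQPNDNKKQKFVVSQIPRADIHMQNHVGLNMIWLDPRSTVVMFQKLSWVSGDNM
>cmpC|aln3
MNHAQMRPHLLIGHMSYSQPGLTPHHNMRDKTAYVAEGRNNKIDAGFQWTHRQTSMACDPVTKMQGHMDRCHACYDYHAQSETYAPDPKYYPSPMCVATRQWFVDSHYAWNMTKCTVFEHHCEKAFTDNQHCAPLAEDGFEYGLLIHQHYMDFKYNNWVMLLTNSWFCVSTPNDNKKFKFVMAQIPVADIHVVNHVLAWCIWTNMRNTVVMWQKLSWASGDNM
>cmpC|aln4
MNGTQAIPHLHIACMSISQPGLTPHHNHRDSTAYVLEQLYLLIDDGDINMCRDTSMACDPMPAMQIHMDRCHACMYYHNQRETRCQSTKYTLMGICVHTRQFFNFCHHATLCGKMHAFEHGFEKDFTDNWHCDPLAEDGFQYGLLYHIHQMDFKYNGWVMGLHNKHFCVSTPNDNKKLWFVVSPMPRADIHVQILVLLNGIWLDMRNKVGPIQKLSWPSGENL
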