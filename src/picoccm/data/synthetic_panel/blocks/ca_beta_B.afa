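>ca_beta_B|aln1
MFVWSYYKMAQYLCSEWGQIGTLAMLVNHTDVNRNLCGDENRFRHNFQVMLRNDQVAKHYFNWKWLICCPWTQGFIAERYAVDPSNYFFGIRVWVKKHDLTSLIESYGARMRNYKLWEYLRTAMWIIECWCHHFKQVQICDEAAHKESHMQVFQDGSFMTMKWVYFNPTNFANPVIQHVGITPKTEVYLERTNWEEMHQHLIWKNAWPPDIDYWEWSFEVPGALPIVPNVDAMSYLWRIYPQLSMSLACTRQVDAQVEGKDSPILIAQTVHRNRDSVTRYVD
>ca_beta_B|aln2
MFVGSYYKMAQYLCMLNGQIGWLAMLVLHTDVTENLCGDENRFCHNFQVYLRNDQVAKHYFNFNWHICCPWTQGFIAERYAVDSSNYFFGICPWVKKHDLTSLIESYGARMMNYKLWEYLLIFMWIIECWCHHFKQVQICDEASHKESHMQVFQLGSFMTMKWVYCNPTNFANPVIQHVHITPMTFVYPERTNWDEMTQHLFWKNAWPPDIDYWEWFFEVPGALPIIPKVDAMSYLWRIYPQLSMMLACTRQPDASVEQFDWPILIICTYHRNRDSVTRYVD
>ca_beta_B|aln3
MWVNSYYRMAQTLCSEWGQIMTLAMEVNHTDVRRNLCGDEPRFDHNRQVMLRNDQVAKHYNNWKWLITQPRTQGYIAEGYAVDPENYFFGIRVWVKKHDLTGLTESYGAAMVSYKLWVYLRTAMWDVEQWCAHFKQSQICDEAAHKGSHFQVFLDNSFMTMKLVNFNPTNNANPVIRHEGITPKTMVYNEVTNWEEMHQFLIWKNAWQPDIDYNKQSFEAPVALPIVTNVDAYSYLWRIYANLSMSLACTRQVDLQVEGKDSPVLIAQTVHRRRDSETREVD
>ca_beta_B|aln4
MFVYSYAKMQQILCSEWGAIYTLAMKVKHTDVFRNLCGDENRFRHNFQVMLRNDQVQKHYFNWKWLICCPWTQGFIARRYATDPSLYFFGIRLWVMDTDLTSLIEWRGAREQEIKLWEYLRTAQFIIECWCHHIWQVQICMEAAHKEIHMQSFDGGDFSTMKWVYFNPTHFAGTVDQKVGIFPFTEFYLGRTNKEEDHQHLIWKMAWPPDIDYWEWSELNNGALPVVINKPNMSYLWNTYPMLSPCFACTRFVDAQLEGKDSPDPIWQTQHRRMPSVTRYVD
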