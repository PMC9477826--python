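>cmpB|aln1
MFGSLEPPMKECVAEQFFPDMNLWSVDYAPNYAFCASNCVQCRGMIKWHCEYQYIFDWQMYPSTEKFCKPERGQAMITYMGTTCETVQFMENYDNMRCFSAIWITDGWSIYLMVVQFPNAMCFKHEGLPWPLAGGTKFWCCDAEVERDLGMWTTTLQGSTIVWKYIVIEQYINARKMHHWVKARGFVEGGAILPCARCPNSIPWIGLGPFRFYRIGTVEWDMSSRWPQSPCNF
>cmpB|aln2
MFGFLEPPMKECVAEQFFPDMILIDVDYAPNYSFCLSNCVQCRGMIKSHCEYQEIFDWQMYPTTEKFCKPEYGQAMITYDRTTCRTVQFMENYCNMRWFSYIWITDGYSIYEMVVSCPNAMCFKHEQLPWPLAGGTKFWCCDAATRTDLGMWHTFLQGSMIVCAYIVIEQYINARKMHHWWKARGFVEGGAILPCARCPRSIPWIGLGPFRFYRIGIVEWDMSSMWPQSRCNF
>cmpB|aln3
MFGSLEPPMKECVARQYMPRMNLISVDYLQTYAFCARNCVQCRRMIKWHCEYQYIQDWMQYPSTEAFCKMRRGQFMITYPGTTCETVRFMCNYDNMRCSSAIWITDVNSIHLRVRQFPNAMCFKHEGLKWPLKGGTKFTACSAEVERDLGMWTTTLQGSTIVWKYILIEQYINMRCAIHWVKIRRQVEGGAQLYHARCPNSIPWSGLGIFRFYRNGTVEWFMSSRKPQSPCNF
>cmpB|aln4
MFGRKEPPMKETVAEQFFPYHNLQSVQYAKNVAFCASNCSQCRGQIPWHCVYQYIFDWMMYPSTEHFCGPERGQAMPTYPGLTCCTVQCVENMDKMSCFSAIWIDDGWSITLMFSYFPNAMCFKIEGLMWPLAGGTSFWCCDAEVERDLGHWTTTLQGTTIVWNYIVIEGYINERIMHHWLKHRYGVWGYGILPCARMPWSIPWIQLGPFIFYRIGMVEWVMRKTWPVPPTNF
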