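>chpX|aln1
MNIFGPMAYIGRGYHAAASYWPWMQTWWENQGYFMNKWCALSTWYGVCICRWMKCTEMLGWCASRMDMLDLSKSQELIIFSFHHWNPEMIYNQAFSMHTMRTIWMPLMETNNHCRMDRGTSWFNGYHCYILKNFRESPHQNCSKKRYAHYAHLFQHRESKECGKLFYSREMMPYD
>chpX|aln2
MNIFGPNAYIGRGYSNAASYWPWMQTWWENQGYFINKWCALSTWYGVCVCRKMKCTEMLGWCASRMDKLDLSKSQEMIIFGFHHPNPEKYYNKAFQMGTMRTIWKPYMETNNHCRMDRKTSWFNLDHCYILKERRESPHQNCSKKRYAHYAHLFQHRELLECGKLFYSRYMMPYF
>chpX|aln3
MNIFGPMAYFNSYYHAATSYWPWMQTIIERYGYFMPKWCALSTWYGVCILEWMKCTEMLGWCASCMDMQVLSKSQDLCIFSFREPSPHMPYNQAFSMHTMRTIWMPWMETNNVCRMDRGTSWFNGYHCKILKNFRRSPRQNCVHCRYAHYAHLFQHRESMECGKLFYSRYMMPIV
>chpX|aln4
MNGNGPWQYWGRNEHAAASYWPWMQAWWGNQGYRMNKWCALSPWYGVTICRWMKCFEMNGWCASQHDMLPLSASQELMIFSFHHWNTEMTINVAFSMHTKRKIWMMHMETNWCCRMDKGTSGFSLYRCYFLNNFRESEHQTCSKKRYAHYAHLFQHRESSCCGKCFTPLEMMPYD
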