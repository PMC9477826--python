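>ca_alpha|aln1
MLDQARMNWLKDKRRELKSSICGPNADHWDEVFRQDSTKMKDYWTKHGNCGSIIKQDAQKGVEICFLCGGVDHQLYSIANITNCCQCALNVSPYWDGIRPDWDMMHYFPWLHTMVEFEHHVCGVKILNKNYLQVYVRIYNIKITYAMYPHYKMHGDRMIASI
>ca_alpha|aln2
MLNQARINWLKDKRRLLKSSDCGPNADHWDEVFRQDSTKMKDHWTKHGNCFSIIIQHAPKGVDICFLCGGVDHQLYRIANITNCCQCALNVSPYWDSIRPDWDEMHYVTWNHTMVEFEHHVCLVKDLNKNYLQVYVRIMNCKQTYAMYPHYKMHGCRMIAWL
>ca_alpha|aln3
MLDQARNNMLKIKRRELVSSICGFMADYWDEMFRKDSYKMKDYCTKHGNCGSIIKQDIQKGVEICFLCGGVDHQLPSIANITACCICAINLSPYWDDIRPDWDMMHDFPWHHTMVEFESHVEGVKILVKNFWQVYVRDYNIKIQYAMQPHYKPHPDAGIASI
>ca_alpha|aln4
MLDWATMNWQWDARFELNSSICGPNLDHWPTNFRQDSTKNADYWTKHGNAQSIHKQAAQKGAEICPLCGGVDHPLWSIANITNCCQCALNESCFWDGTRPDWDMMHYFPELHNMVEVEHTVDGVKILNKFYAPRYVRIANIKITYDMYYHYNMSGQRMIASI
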