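>ca_epsilon|aln1
MMGPYGGTDSGDAGYSWKWVDCSFLMMNCKLTVDAKQVQPIMGRPACDQETNQHTEKKKSDWIKQYIMWTLNCIWAERKGGHFPKWPNNALMNNSYFPIMYIQMDSHASCVHCGQWDWHTDIMWASSLDSQFYIGWQVGIDGTVIVSWKLRYSEPDRADDIHNDCAVVITEPMISM
>ca_epsilon|aln2
MMGPYGGCDSGDAGYGWKWVDCMFLMMNCKLTVDAKQVQPIMGRPACAQMTNGATEDKKSDWIKQPIMWTLNCMWAERKGYHFPLWPNWELFNNSYFPIMYRLHDSHASCVACGQWDWHTDIMWASPLDSQFYIGWQVGIDGTVIVSWHQRYREPDRGDDIHNDCAVVIIEPMISW
>ca_epsilon|aln3
MMGYYGPTDSGDAGYSWKWVDCSFLMTRCKLTVDADQVQPIMFQPACFQETNQHTEKKKVDWYNQYIMWTLNCIWIYRHGGEFPSLPNAALMNNHYGPLSNIQMDMHASCVMCAQWDWTTWIMWISSLDSQFKIGGQVGIWGYVIVSWKLRYSEDDRADDIKNDCAVVITEPMISM
>ca_epsilon|aln4
MMYPAGGYDSGDAGYYWKWVDCSFLMLNCKVTVDDKQEQPIMGRPSCDESTQQHTNKFVEDWIKQYIEITLNCIWYEMKGGHFPKWPPNAVMNNSFFPIMTIEMDCHASQVNCGQGDWHTDDMWISSLDSQFYIGQFVIIRGKEIVSWDPRYSAPDWADDIHTDCAVVIVERMISM
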