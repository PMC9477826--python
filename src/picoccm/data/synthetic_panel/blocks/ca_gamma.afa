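>ca_gamma|aln1
MCCVCKGMWVANSAPRPWAQERHHVDQFDSTTLQSKEFLSLKVPHQQLFERHSYEVPTRAYHLPVDPAFDVEDELGRPHWNTHQPTDAEYLPNISVHHPYRGFGANKMSGFFMIHHFSVVGPECCPLLYTPKMCFLQFAFDYFRCTASQGHSVMSFLWTQWDFDGDANSCPKQNLMAFGFTTKLFDLNYWWQHRWPMWELNCPQGLYTRRQNGVMNGDHCNAPITCQPLLKCRENKVCEKVYDMHQAQPFQYCVVF
>ca_gamma|aln2
MCDVCKGMWVANSAPWPWWQERHHVDQFIITTLQSKFCLSFKVRHQQLFERHSYEVPTPAYHLPVDPASDVEDELGRPHWNLHQPEDAKYLPCISVHHPYRWFGANKMSGFHMMHHFSVVGPECCPLLYTPKYCFLQMAFDYFKCTASQHHSVMTFLWTQRDFDGDANFQPKQNCWAFGFTTKLTDLNYWWQHRWPWWELKCPQGLYTRRGYGVMNGDSCNAPLTCQPILKCREAKVCEKVYDMHQAMPFQYCVVF
>ca_gamma|aln3
MCCVCKGWWVLNSAPRPWAQERHHVDQFDFTTLQSKEFLPLMVKHFQLFERHGYEVGTRAYHEPVDPAFDVELELGRPHPNTHWPTCAEYLPNISVHHPYAGFGNNKMSGFFEIHHFSMVGVECCPDLYTPKMTFLQFAQDYFCCTASQGHSVMSFENTQVDPDGDINMCPKQNLMAFGFTWKLSDLNYNWQHRWPMWECNQPHGHYSRRQNGVMNGDTCYRPIHTQNLLYCRENIVCHKVYCYHQFQPFQYPVVI
>ca_gamma|aln4
MCCGCKGMGVANSAKRPWATERHHVDQFGSTTLQSHSFLVLCVPHQQLFCRHSYQVPTRAYHLPTDYAFDVEDPLVAGHWGTWQPQSLEFLPNYSVHHPSRYRGALKMSGFSAIHHFSVVGPWCRPLLYMPKMCDIQEAFDYWWCMASQTHWVMSFWWTQWPFDKDANSCMKANNMAFGFTMKLFDLWYHTKHRWPMKELNCPQGLYTVRQNETMMGSNCNYPITCQPLLKCRENMVCEKVYDMHLFQPFQYCPVF
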