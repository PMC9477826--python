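>ca_beta_A|aln1
MFMYKNCKPTNQIIKKPEIESACDWLNIGTVWNTSCFEQEPELASLSGMILAQGVMGEDCEATSQFWGKMSTDTGNGFDKTGWLVNVPWWFWIFNWSSSGDTNTKLWQKNPGIVIAIVHTWLVGEDMVEAWVWLVGSEILEKTAYIWDFTGIEQERMFFVTIAIQPHTRKEYTCRCVNDQPYFIGPDNTMYHEWDVAFWLDDLQGDKRHMGNDDNKQIMWGVYQSGAGPMNCGGDTPSKMQGWHEHCYPNMHSYA
>ca_beta_A|aln2
MFMYKNCKPVNQRISSPFIESACDWLNIGTVWKTSCFEQEPNLASASGMTLAQGVMGLDCKATSQFMGWMSTDTGNGFDKYGWLVNVWWWPWIFNWSSSGCTETKGWQKQPGMVIAIFHTWLVGEDMVQAWMWLVGSEILEKTAYIWDFTGIEWERMFFVTIAIQPHRRKEYTCRCVNDQPYFIGPDNTIGHEWDVAIWEDDLQGDERHLGNDDHKQIGWGVYQSGAGPPNCGVDHPSKMQGRHEHCYPNMHSYA
>ca_beta_A|aln3
MFNYKNCKPTNQIKKKPEIESACLWLNIGTGWNHSTFEQEPELASASNMHWDQGVMIEDCEATSKFTGKMSPDTGNGFLKTNKQVNVPWWFPIFNSSSSGGTNTKLWQKNPRIVINIVAAFLVGMDDVEAWVWLVDSECLEKTRPIWDFTGIEDEGMFFVTIAIQPHTKTEYTCRCVNDWPCFIGPDATMYHEWDVAFWLRDLQGDKRHMGNDDNKQIMWDVYQSGAGPMEPGGCSPSIMQGNIEICYPKMHSYA
>ca_beta_A|aln4
MFMHKNCKPTVKEIKKTEQESHCDWLWIRTVWNTSWFWQEPELAMLWGQIDAQHVYVEDCLATSQPKGTMSFDTGQGFDKTGWLFNVPWWFWEFNPSHRGDTNWKLWQAIPGIWIAIVKWWLVGEDMVEAWSLLVGSEIDEKTHYQWDFTGIEQQRMFFVTIAIMRETRFEYEIRCVTDQPVFMGPDNTMYHDWDVAFWLDDLQCDPRTMGNYDNYQIMQLVYQSGRSPMNCGGFHPSKMQGWGEHCYPNMHSYN
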