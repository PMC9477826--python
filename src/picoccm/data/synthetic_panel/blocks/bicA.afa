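>bicA|aln1
MYANYASELTADLGNIMQMKTWHYTNAQFQKWNWQIFMNHHMNGTWELFNCYKWWWCGSVGHEQWFNHELNVVFYVPTNKNQRFLKLPLSDVKLGQNIAKFTTEIAFDCQQNLLSQLDNWWRQAHHRTADYEKEWICDNCIPPWSAWTSRMNKCGRISAVDDRFHC
>bicA|aln2
MYAWYAVELTTVLGNIMQMKTWHYTNAQWQKWNWQIFMNCHMNGTWELSNCSMWWPCGTVPHEQWFNHFLNVVFYVMTNKNQRFDKLPLSDVKLGQNIAKFTTEIANDCQQNLLSQYPNGWRQAHHRTAGYEKHWICDNVIPPKSANTSRGNKCGRISAVDDRFHC
>bicA|aln3
MWANYAAELGASLNNIMQMKTWHYTNAQQQVWNWQIFMNHHMQGGWELFNCYKWWWNGSVTPEDWFNHELSHVFGVPTNKNQRFLKLPLSDFIYGQNDAKITTEIAYDCQQNLLSNLENWWRQAHHRPAELDKEWICYNEIPPWSAWTSRMNKCGCISAVDDWRHC
>bicA|aln4
MYAWYASGPTSELGNAIVMKTHKYTNAQFQKWNMIIFMNFHMAGTREAFNCYKWWWCGSVAHEQWFNHLFNVVFYVPQPNNDRFLKLPLQDVKEGQNIAKFKEEIAFHCNQPTLSQLYNWWYQAEHRCADYEKNCICDNCIPPNFAWTSRFNLCGRESAVDDRFHC
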