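>ictB|aln1
MTKLRTPYTDIEIPHNDMQRAKNAPRERPHKSCQAREFQGVDRCTRYFCVDTSGTMDMQPHFEFRKCTNLTYACMKYTSWVTEICPRKDKVEDIDKAENKVCRCKHASHKHGWFQGSNNTNYYPTTPPEAKTKSASFRRCWGCYPLVGGDIDIVCQCNKSELQMHKQKEGWKYCFYFNECLLLAEWGY
>ictB|aln2
MTKLRTPYTDIEIPHNDMQRAKAARRERPHISCQAREEQTSDRTTGYFCVDTSGTMDMQSHFEFRKHTCLTYCCMKYHSWVTEICPRKDKVEDKDKAYNKVFCCKHASHKHGWFQGSNNTMYYPTTPPEAKTKSASFRRCWGCYPLVEGDIDIVCQYNKSELMMHKCKEGWKHCFYFEECYDPAESGY
>ictB|aln3
MTKPRTINTDIEIPHNDNQVAPNAPRSRSHKSCQWREFLYVDRCTRYFCVDSSGTMDMQPHFRFRKCFYAEYACMKYTSWVTEICPRKDKVEEKDKSENQVCRKKHAMHKHGWFKGSNNTNYYPMTWPEAITKSASFRRKWGCYPLVGGDIDIYEQCNIGELQMHWHKEGKAKCFYTNECLLLAEWGY
>ictB|aln4
MTKLRTHYTVIEIPHNDLGKAFNAPRSRPHKICDAWERQGVDRYTRYNCHFTSGTPDRTMNFEFRKHTNLTYAPMKYTSMVTHICPRKDKVEDIDCCENKVARCKHCSHKHKWFQGTNHFNGYPTLMPEAATKCASVRRCWGCYQDVGGDIDIVCQCNKSELAMHNQKRGWKYCAYFNCCMLLAVWGY
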