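>RII_like_synthetic_ref synthetic RII-alpha-like extended D/D reference window (77 aa)
MSVTIYVTQYGAELLEKAMQALPAGLDEAVEYFELLAKEASRVSEFNPDEWAEKMEANKE
LLSRQEAGEIDPKAVSE
>consensus_DPY30 synthetic DPY-30-like consensus (77 aa)
MDPEQLSRETTEQLLNEGLQTIASGQEDLVKMMELQNLDAGEQKTPDALNSMSKDVESLR
AKIEGFEATPAGSNEKV
>consensus_R1D2 synthetic type-I-like (R1D2) consensus (77 aa)
MAELEQKALESAELLRKAMQALPTDPEEAVEWLELLAKEASRVSEFNADEWTEKMEANRE
LLTRQEAGEVDPKAISE
>consensus_R2D2 synthetic type-II-like (R2D2) consensus (77 aa)
MSVTIYVTQYGAELLEKAMQALPAGLDEAVEYFELLAKEASRVSEFNPDEWAEKMEANKE
LLSRQEAGEIDPKAVSE
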