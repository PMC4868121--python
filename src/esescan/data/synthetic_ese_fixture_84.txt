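# synthetic purine/adenine-biased hexamer fixture set (84 motifs)
# stand-in for a high-confidence ESE collection; not a published set
GGAAAG
AAGACT
ACATTC
AGTAAC
CTATAA
AAACGT
GCCTCC
GTCAAC
GGGAGC
GAGAAG
CTGCCA
GAGGGA
CTGAGG
AAAGAA
GTACTA
GTATTA
AAAAAT
ACACAA
AGGAGG
AAAAAA
TCAAGA
AGGACC
GAGCCA
ACAGTA
GTAGCA
TCCAAG
TACGGA
CAAAAA
GAAAAA
AAAGGC
AGTGCC
TATATG
GCAAGA
GCAACT
AAAAAC
CAGGAA
CTTAAA
CGACGA
CACAGC
GTAATG
CCGAGA
GTGAAG
TAACGA
AAACAA
AATCCG
GCAACA
GGATGA
CGAAGC
CAATAG
CGGAGG
GCAGAG
AAGACG
AACGGG
TAAAAT
GCTGTA
CCCAGA
AAGCAA
ACGGTA
AGGGAT
AGGAAA
GAGGCA
AATACT
ACCGCA
AGTAAA
CACAAT
CGGTGA
CGACCG
ATGAAG
TAAGCA
ACAGAA
GGGAAA
AGAGGA
ACCGAA
AAGGAG
AAGACA
CGGCCT
AAACAG
ACCGGG
GAAGCC
CGGGTG
ATAAGA
CAAGCG
GTGAGC
AGCAAA
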