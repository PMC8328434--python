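>ITS_F
GAAACTGCGAATGGCTC
>ITS_R
TTGGTCCGTGTTTCAAGACG
>3770F
GATCCGGTGAACCTTCTGGAC
>2104R
CGGCGCTTTATCCTATTTTGGC
>3770F_GC
CGCCCGCCGCGCCCCGCGCCCGTCCCGCCGCCCCCGCCCGGATCCGGTGAACCTTCTGG
AC
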