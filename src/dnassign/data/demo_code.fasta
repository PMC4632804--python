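>s mode=labeled t=5
CTATC
>e mode=labeled t=5
AACTC
>A1 mode=labeled t=5
TAAAA
>A2 mode=labeled t=5
CTTTT
>A3 mode=labeled t=5
TTCAA
>B1 mode=labeled t=5
AATTA
>B2 mode=labeled t=5
CATTA
>B3 mode=labeled t=5
ATCTA
>B4 mode=labeled t=5
CAAAC
>B5 mode=labeled t=5
ATCCA
>w_1_1 mode=labeled t=5
CCCAT
>w_1_2 mode=labeled t=5
ATATA
>w_1_3 mode=labeled t=5
TTACA
>w_1_4 mode=labeled t=5
TACCC
>w_1_5 mode=labeled t=5
TTCTT
>w_2_1 mode=labeled t=5
TTTCA
>w_2_2 mode=labeled t=5
ATAAT
>w_2_3 mode=labeled t=5
CTACC
>w_2_4 mode=labeled t=5
TTACA
>w_2_5 mode=labeled t=5
CATAC
>w_3_1 mode=labeled t=5
CCTTC
>w_3_2 mode=labeled t=5
ACTCA
>w_3_3 mode=labeled t=5
TCACT
>w_3_4 mode=labeled t=5
ACCCT
>w_3_5 mode=labeled t=5
TTAAC
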