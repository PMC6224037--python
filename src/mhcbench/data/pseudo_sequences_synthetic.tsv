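allele	pseudo
HLA-A0101	YFAMYQENMAHTDANTLYIIYRDYTWVARVYRGY
HLA-A0201	YFAMYGEKVAHTHVDTLYVRYHYYTWAVLAYTWY
HLA-A0301	YFAMYQENVAQTDVDTLYIIYRDYTWVARVYRGY
HLA-A2402	YSAMYEEKVAHTDENIAYLMFHYYTWAVQAYTGY
HLA-B0702	YYSEYRNICTNTYESNLYLRYDSYTWAVLAYLWY
HLA-B2705	YHTEYREICAKTDEDTLYLNYHDYTWAVLAYEWY
HLA-B3801	YHSEYRNICTNTDESNLYLRYDDYTWAELAYLWY
HLA-B4403	YYTKYREISTNTYENTAYIRYDDYTWVVLAYEWY
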