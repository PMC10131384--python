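# Synthetic crude-count reconstruction of thyroid-cancer (THCA) incidence
# for four continental registry aggregates: case counts are back-derived
# from published age-standardized rates per 100,000 (treated here as crude
# rates) and registry person totals split evenly by sex. For the Z test's
# input contract only; not registry microdata.
population	sex	cases	persons
Africa	male	20	2732989
EastAsia	male	1674	53823369
Europe	male	1512	50908271
SouthAsia	male	257	25491958
Africa	female	92	2732989
EastAsia	female	5302	53823369
Europe	female	4297	50908271
SouthAsia	female	665	25491957
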