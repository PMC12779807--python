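age_class,sex,count
<45,F,19954
<45,M,31038
45-54,F,52459
45-54,M,71144
55-64,F,132230
55-64,M,142807
65-74,F,267700
65-74,M,204546
75-84,F,230768
75-84,M,126125
>84,F,28099
>84,M,11530
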