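age_group,standard_population
0,13818
1-4,55317
5-9,72533
10-14,73032
15-19,72169
20-24,66478
25-29,64529
30-34,71044
35-39,80762
40-44,81851
45-49,72118
50-54,62716
55-59,48454
60-64,38793
65-69,34264
70-74,31773
75-79,27000
80-84,17842
85+,15508
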