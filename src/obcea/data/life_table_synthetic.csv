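age,year,remaining_life_expectancy
0,2000,57.4
5,2000,58.1
10,2000,53.6
15,2000,48.9
20,2000,44.4
25,2000,40.1
30,2000,35.9
35,2000,31.8
40,2000,27.8
45,2000,23.9
50,2000,20.2
0,2012,61.2
5,2012,61.3
10,2012,56.6
15,2012,51.8
20,2012,47.2
25,2012,42.7
30,2012,38.3
35,2012,34.0
40,2012,29.8
45,2012,25.7
50,2012,21.8
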