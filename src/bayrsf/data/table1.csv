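individual,sex,scl_cm,tracking_start,duration_days,n_fixes,n_eff
1,F,100.5,2013-06-04,92.6,81,81
2,F,109.3,2014-03-13,75.5,189,189
3,F,95.0,2014-05-13,100.7,201,201
4,U,65.8,2014-06-10,29.2,43,43
5,M,102.6,2014-06-15,27.9,7,7
6,F,100.8,2014-06-26,68.7,216,216
7,F,99.0,2014-07-01,34.3,113,113
8,U,75.2,2015-08-27,19.3,66,66
9,F,102.5,2015-08-28,23.3,69,69
10,F,94.8,2015-12-08,18.9,85,30.5
11,F,101.3,2016-05-10,52.9,42,42
12,U,69.2,2016-06-01,13.3,52,39.7
13,U,80.4,2016-06-15,33.1,33,33
14,U,62.3,2016-06-15,34.4,140,87.6
15,U,65.4,2016-06-29,29.5,145,97.7
16,U,71.0,2016-06-29,44.8,309,195.0
17,U,71.3,2016-07-13,21.2,221,101.4
18,U,79.7,2017-05-11,47.0,105,82.1
19,U,61.6,2017-05-25,13.3,110,27.9
20,U,75.8,2017-06-08,16.8,112,71.1
21,U,83.0,2017-06-09,16.6,6,6
22,U,53.2,2017-06-22,38.1,26,15.8
23,F,90.5,2017-06-22,80.1,241,147.6
24,U,40.0,2017-06-22,24.8,103,58.3
25,M,88.1,2017-06-23,20.2,33,27.7
26,M,66.5,2022-06-09,40.9,134,134
27,F,95.3,2022-09-08,205.9,1039,738.4
28,U,63.3,2022-09-08,175.9,671,571.7
29,F,83.3,2022-09-22,158.8,431,298.9
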