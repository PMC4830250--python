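case_id,sex,age,planimetry_mL,v1,v2,v3,v4,v1p,v2p,v3p,v4p
1,F,82,9.85,19.84,8.38,12.54,7.38,13.93,9.85,9.74,9.43
2,M,64,60.74,91.14,51.26,74.95,44.50,66.69,65.60,58.42,57.68
3,F,62,52.46,82.27,42.92,76.91,43.47,60.13,54.76,59.95,56.34
4,M,61,3.22,4.91,2.95,4.91,2.95,2.88,2.79,3.79,3.66
5,M,58,34.41,48.77,28.45,43.20,27.90,35.34,35.94,33.66,36.10
6,M,58,17.17,27.39,15.00,24.65,14.08,19.52,18.46,19.19,18.14
7,M,58,17.77,26.35,15.15,26.35,15.15,18.75,18.65,20.51,19.52
8,M,56,6.81,8.58,5.36,8.58,5.36,5.60,5.93,6.65,6.80
9,M,54,11.47,17.80,9.24,17.80,9.24,12.42,10.97,13.84,11.84
10,M,52,5.41,7.81,4.68,7.81,4.68,5.03,5.05,6.05,5.92
11,M,50,7.58,9.73,5.95,9.73,5.95,6.45,6.69,7.55,7.56
12,M,50,12.26,18.04,10.15,18.04,10.15,12.60,12.15,14.03,13.02
13,F,48,27.35,30.91,24.96,22.75,20.12,22.12,31.41,17.70,25.99
14,F,48,22.55,25.41,18.22,25.19,18.06,18.05,22.64,19.61,23.31
15,M,48,7.08,8.34,5.45,8.85,5.79,5.42,6.05,6.86,7.35
16,M,48,8.65,13.59,7.72,13.59,7.72,9.31,9.00,10.56,9.87
17,M,47,16.17,29.07,14.53,26.46,13.23,20.76,17.85,20.60,17.03
18,M,47,9.76,15.60,6.38,11.91,5.41,10.79,7.25,9.25,6.87
19,M,47,33.03,47.02,26.72,36.05,22.94,34.04,33.69,28.08,29.65
20,M,45,91.37,114.31,70.42,110.36,69.96,83.84,90.51,86.04,90.78
21,M,45,25.46,27.34,19.36,30.49,21.60,19.48,24.13,23.74,27.91
22,M,45,46.04,54.53,35.35,54.53,35.35,39.61,44.91,42.50,45.78
23,M,45,13.18,19.30,10.81,17.13,10.28,13.53,13.01,13.33,13.20
24,M,43,55.81,77.30,40.92,73.39,41.01,56.45,52.16,57.21,53.15
25,M,43,32.63,37.19,24.57,37.14,24.54,26.77,30.91,28.93,31.73
26,F,43,7.01,10.06,6.11,10.06,6.11,6.70,6.90,7.81,7.77
27,F,42,33.01,58.06,31.67,58.06,31.67,42.21,40.13,45.24,41.00
28,M,42,39.26,59.97,33.32,59.18,32.88,43.63,42.27,46.12,42.57
29,M,41,9.21,12.04,6.83,12.04,6.83,8.16,7.83,9.35,8.70
30,M,40,14.47,27.18,12.23,27.18,12.23,19.37,14.86,21.16,15.73
31,M,37,32.62,47.44,29.96,40.97,25.87,34.35,37.91,31.91,33.47
32,M,37,12.72,16.36,10.11,17.25,10.65,11.36,12.10,13.42,13.68
33,M,36,11.65,18.29,8.49,16.29,9.31,12.78,10.00,12.67,11.93
34,M,35,239.98,315.83,184.23,296.42,185.26,232.96,238.46,231.17,240.67
35,M,35,22.10,23.14,15.43,23.14,15.43,16.37,19.02,18.01,19.89
36,M,34,54.27,64.49,38.69,58.37,39.69,46.97,49.26,45.49,51.43
37,M,33,40.70,54.88,30.13,51.73,28.40,39.86,38.13,40.31,36.75
38,M,32,8.42,13.81,7.77,12.10,7.18,9.47,9.06,9.40,9.17
39,M,30,24.90,36.22,20.70,34.74,19.85,26.06,25.87,27.06,25.64
40,M,30,40.44,62.27,34.25,51.81,28.50,45.33,43.48,40.37,36.88
41,M,28,92.91,123.92,74.67,123.80,76.18,90.95,96.03,96.52,98.87
42,M,27,15.94,21.40,13.91,19.06,12.39,15.09,17.04,14.82,15.93
43,M,26,5.60,7.26,4.48,7.09,4.59,4.62,4.79,5.49,5.80
44,F,26,20.54,25.59,15.49,14.14,12.83,18.18,19.09,10.99,16.52
45,F,25,9.08,11.60,6.82,11.60,6.82,7.83,7.83,9.01,8.70
46,F,25,18.27,27.21,15.04,27.21,15.04,19.39,18.51,21.18,19.38
47,M,25,17.81,24.55,14.03,23.93,14.24,17.42,17.20,18.62,18.34
48,M,23,52.86,71.34,40.36,53.31,38.23,52.04,51.43,41.54,49.53
49,M,23,146.92,204.97,111.53,200.68,112.14,150.93,143.95,156.49,145.61
50,F,22,45.23,56.78,35.01,55.90,35.87,41.26,44.48,43.56,46.46
51,F,22,13.71,17.29,10.81,17.29,10.81,12.04,13.01,13.45,13.88
52,M,19,15.71,21.88,12.76,21.88,12.76,15.44,15.55,17.02,16.42
53,F,19,7.35,8.41,5.46,8.41,5.46,5.47,6.06,6.52,6.93
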