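# provenance: per-angle mean/SD summary transcribed from a published 3D-CT reference cohort
# cohort: 142 normal adult hips (76 male, 66 female) measured every 5 deg of APP tilt from -30 to +30
# units: acea/lcea in degrees, coverage as a fraction; n is the hip count per group
app_tilt_deg,measure,group,mean,sd,n
-30,acea,overall,9.61,8.76,142
-30,acea,male,11.71,9.5,76
-30,acea,female,7.19,7.17,66
-30,coverage,overall,0.65,0.09,142
-30,coverage,male,0.67,0.09,76
-30,coverage,female,0.63,0.08,66
-30,lcea,overall,26.95,7.67,142
-30,lcea,male,30.22,7.26,76
-30,lcea,female,23.18,6.32,66
-25,acea,overall,13.62,8.83,142
-25,acea,male,15.86,9.49,76
-25,acea,female,11.06,7.25,66
-25,coverage,overall,0.69,0.09,142
-25,coverage,male,0.71,0.09,76
-25,coverage,female,0.67,0.08,66
-25,lcea,overall,28.61,7.38,142
-25,lcea,male,31.67,7.01,76
-25,lcea,female,25.09,6.15,66
-20,acea,overall,17.53,9.02,142
-20,acea,male,19.95,9.54,76
-20,acea,female,14.75,7.53,66
-20,coverage,overall,0.73,0.1,142
-20,coverage,male,0.75,0.09,76
-20,coverage,female,0.72,0.09,66
-20,lcea,overall,30.27,7.19,142
-20,lcea,male,33.11,6.97,76
-20,lcea,female,27.0,5.97,66
-15,acea,overall,21.7,9.1,142
-15,acea,male,24.16,9.7,76
-15,acea,female,18.87,7.48,66
-15,coverage,overall,0.76,0.08,142
-15,coverage,male,0.78,0.09,76
-15,coverage,female,0.75,0.08,66
-15,lcea,overall,31.66,7.0,142
-15,lcea,male,34.44,6.82,76
-15,lcea,female,28.45,5.75,66
-10,acea,overall,25.69,9.14,142
-10,acea,male,28.26,9.83,76
-10,acea,female,22.73,7.29,66
-10,coverage,overall,0.79,0.08,142
-10,coverage,male,0.81,0.08,76
-10,coverage,female,0.78,0.07,66
-10,lcea,overall,33.11,6.94,142
-10,lcea,male,35.9,6.73,76
-10,lcea,female,29.89,5.71,66
-5,acea,overall,29.74,9.16,142
-5,acea,male,32.42,9.81,76
-5,acea,female,26.65,7.27,66
-5,coverage,overall,0.81,0.07,142
-5,coverage,male,0.83,0.07,76
-5,coverage,female,0.8,0.07,66
-5,lcea,overall,33.89,6.77,142
-5,lcea,male,36.66,6.52,76
-5,lcea,female,30.7,5.57,66
0,acea,overall,33.84,9.29,142
0,acea,male,36.75,9.83,76
0,acea,female,30.48,7.36,66
0,coverage,overall,0.84,0.07,142
0,coverage,male,0.85,0.07,76
0,coverage,female,0.82,0.06,66
0,lcea,overall,34.74,6.65,142
0,lcea,male,37.41,6.5,76
0,lcea,female,31.67,5.4,66
5,acea,overall,37.46,9.32,142
5,acea,male,40.42,9.8,76
5,acea,female,34.05,7.45,66
5,coverage,overall,0.84,0.06,142
5,coverage,male,0.86,0.06,76
5,coverage,female,0.83,0.06,66
5,lcea,overall,34.95,6.55,142
5,lcea,male,37.42,6.42,76
5,lcea,female,32.11,5.48,66
10,acea,overall,41.15,9.52,142
10,acea,male,44.29,9.86,76
10,acea,female,37.55,7.71,66
10,coverage,overall,0.85,0.06,142
10,coverage,male,0.87,0.07,76
10,coverage,female,0.84,0.06,66
10,lcea,overall,35.13,6.61,142
10,lcea,male,37.47,6.54,76
10,lcea,female,32.43,5.62,66
15,acea,overall,44.68,9.81,142
15,acea,male,48.05,10.06,76
15,acea,female,40.8,7.96,66
15,coverage,overall,0.84,0.06,142
15,coverage,male,0.86,0.06,76
15,coverage,female,0.84,0.06,66
15,lcea,overall,34.76,6.67,142
15,lcea,male,37.0,6.66,76
15,lcea,female,32.18,5.71,66
20,acea,overall,48.16,10.12,142
20,acea,male,51.67,10.3,76
20,acea,female,44.12,8.3,66
20,coverage,overall,0.84,0.06,142
20,coverage,male,0.85,0.07,76
20,coverage,female,0.83,0.06,66
20,lcea,overall,34.36,6.89,142
20,lcea,male,36.51,6.93,76
20,lcea,female,31.89,6.0,66
25,acea,overall,51.56,10.61,142
25,acea,male,55.31,10.81,76
25,acea,female,47.24,8.6,66
25,coverage,overall,0.84,0.06,142
25,coverage,male,0.85,0.07,76
25,coverage,female,0.83,0.06,66
25,lcea,overall,33.7,7.04,142
25,lcea,male,35.77,7.14,76
25,lcea,female,31.3,6.14,66
30,acea,overall,54.91,11.05,142
30,acea,male,58.77,11.2,76
30,acea,female,50.46,9.08,66
30,coverage,overall,0.83,0.07,142
30,coverage,male,0.84,0.07,76
30,coverage,female,0.82,0.06,66
30,lcea,overall,32.96,7.14,142
30,lcea,male,34.81,7.44,76
30,lcea,female,30.84,6.19,66
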