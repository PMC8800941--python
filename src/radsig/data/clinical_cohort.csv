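patient_id,lesion_index,stage,grade,pcr,bl_suv_mean,bl_sul_peak,bl_suv_max,d_suv_mean,d_sul_peak,d_suv_max
1,1,IIB (T2N1),2,No,1.86,1.57,4.03,,,
2,1,IIB (T2N1),3,Yes,6.59,4.58,11.27,-60.97,-68.11,-57.82
3,1,IIIA (T3N1),3,No,10.55,12.34,26.41,,,
4,1,IIA (T2N0),,Yes,8.77,7.80,21.48,-75.49,-82.21,-86.77
5,1,IIB (T2N1),3,No,3.18,1.64,5.31,-4.32,-13.19,-9.40
6,1,IIB (T2N1),3,No,2.92,1.29,4.54,-38.67,-41.17,-41.77
6,2,IIB (T2N1),3,No,8.01,6.43,15.55,-40.82,-44.37,-42.90
7,1,IIB (T2N1),3,No,8.58,6.20,17.02,-64.92,-70.33,-73.40
7,2,IIB (T2N1),3,No,8.91,6.62,20.11,-62.72,-68.17,-61.72
8,1,IIA (T2N0),3,Yes,2.49,1.61,5.25,,,
9,1,IIA (T2N0),3,Yes,4.17,3.06,12.45,-48.84,-48.53,-64.23
10,1,IIA (T2N0),3,Yes,3.89,3.12,8.62,-57.76,-59.91,-73.72
11,1,IIB (T2N1),3,No,2.85,2.59,6.28,-41.45,-55.68,-55.97
11,2,IIB (T2N1),3,No,2.48,2.03,5.03,-27.04,-37.81,-49.88
12,1,IIA (T2N0),3,No,8.66,7.56,21.87,-75.82,-82.48,-81.35
13,1,IIB (T2N1),3,Yes,10.29,8.32,28.33,-74.14,-76.39,-81.07
13,2,IIB (T2N1),3,Yes,3.64,2.02,5.65,-58.93,-57.11,-55.17
13,3,IIB (T2N1),3,Yes,8.00,5.60,16.06,-71.75,-77.22,-77.14
14,1,IIA (T2N0),3,Yes,1.86,1.65,4.18,-30.42,-36.91,-53.02
15,1,IIA (T2N0),3,No,9.80,7.74,17.69,-67.65,-64.44,-54.15
16,1,IIA (T2N0),3,Yes,7.19,5.21,14.57,-46.36,-42.49,-43.23
17,1,IIA (T2N0),3,No,7.98,7.26,18.46,-45.99,-54.32,-42.74
18,1,IIA (T2N0),3,Yes,2.91,2.03,5.24,-40.23,-40.04,-58.66
19,1,IIB (T2N1),3,Yes,6.19,5.53,11.28,-69.81,-74.57,-76.91
20,1,IIB (T2N1),3,No,2.44,1.99,5.53,,,
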