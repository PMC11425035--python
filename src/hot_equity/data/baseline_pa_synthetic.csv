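# synthetic baseline leisure-time physical-activity quantile table
# (MET-hr/week): 25% inactive, log-normal active tail, capped at 150.
# Constructed stand-in; not estimated from any cohort.
probability,met_hr_week
0.0,0.0
0.005,0.0
0.01,0.0
0.015,0.0
0.02,0.0
0.025,0.0
0.03,0.0
0.035,0.0
0.04,0.0
0.045,0.0
0.05,0.0
0.055,0.0
0.06,0.0
0.065,0.0
0.07,0.0
0.075,0.0
0.08,0.0
0.085,0.0
0.09,0.0
0.095,0.0
0.1,0.0
0.105,0.0
0.11,0.0
0.115,0.0
0.12,0.0
0.125,0.0
0.13,0.0
0.135,0.0
0.14,0.0
0.145,0.0
0.15,0.0
0.155,0.0
0.16,0.0
0.165,0.0
0.17,0.0
0.175,0.0
0.18,0.0
0.185,0.0
0.19,0.0
0.195,0.0
0.2,0.0
0.205,0.0
0.21,0.0
0.215,0.0
0.22,0.0
0.225,0.0
0.23,0.0
0.235,0.0
0.24,0.0
0.245,0.0
0.25,0.0
0.255,0.673
0.26,0.872
0.265,1.026
0.27,1.159
0.275,1.278
0.28,1.389
0.285,1.494
0.29,1.594
0.295,1.69
0.3,1.783
0.305,1.874
0.31,1.963
0.315,2.05
0.32,2.136
0.325,2.221
0.33,2.305
0.335,2.388
0.34,2.471
0.345,2.553
0.35,2.634
0.355,2.716
0.36,2.797
0.365,2.878
0.37,2.959
0.375,3.04
0.38,3.122
0.385,3.203
0.39,3.284
0.395,3.366
0.4,3.448
0.405,3.53
0.41,3.613
0.415,3.696
0.42,3.779
0.425,3.863
0.43,3.948
0.435,4.033
0.44,4.118
0.445,4.204
0.45,4.291
0.455,4.378
0.46,4.466
0.465,4.555
0.47,4.645
0.475,4.735
0.48,4.826
0.485,4.919
0.49,5.012
0.495,5.105
0.5,5.2
0.505,5.296
0.51,5.393
0.515,5.491
0.52,5.59
0.525,5.69
0.53,5.792
0.535,5.894
0.54,5.998
0.545,6.103
0.55,6.21
0.555,6.317
0.56,6.427
0.565,6.537
0.57,6.65
0.575,6.764
0.58,6.879
0.585,6.996
0.59,7.115
0.595,7.236
0.6,7.358
0.605,7.482
0.61,7.609
0.615,7.737
0.62,7.867
0.625,8.0
0.63,8.135
0.635,8.272
0.64,8.411
0.645,8.553
0.65,8.698
0.655,8.845
0.66,8.995
0.665,9.148
0.67,9.304
0.675,9.462
0.68,9.624
0.685,9.79
0.69,9.958
0.695,10.131
0.7,10.307
0.705,10.486
0.71,10.67
0.715,10.858
0.72,11.051
0.725,11.247
0.73,11.449
0.735,11.655
0.74,11.867
0.745,12.084
0.75,12.307
0.755,12.536
0.76,12.771
0.765,13.012
0.77,13.26
0.775,13.516
0.78,13.779
0.785,14.05
0.79,14.329
0.795,14.617
0.8,14.915
0.805,15.223
0.81,15.541
0.815,15.87
0.82,16.212
0.825,16.566
0.83,16.934
0.835,17.316
0.84,17.714
0.845,18.128
0.85,18.561
0.855,19.013
0.86,19.486
0.865,19.981
0.87,20.502
0.875,21.049
0.88,21.626
0.885,22.235
0.89,22.88
0.895,23.565
0.9,24.294
0.905,25.072
0.91,25.905
0.915,26.801
0.92,27.768
0.925,28.818
0.93,29.962
0.935,31.219
0.94,32.607
0.945,34.153
0.95,35.892
0.955,37.872
0.96,40.157
0.965,42.842
0.97,46.068
0.975,50.067
0.98,55.238
0.985,62.377
0.99,73.391
0.995,95.029
1.0,132.486
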