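sex,age_years,fm_mean,fm_sd,lm_mean,lm_sd,bmc_tb_mean,bmc_tb_sd,bmd_tb_mean,bmd_tb_sd,bmd_ls_mean,bmd_ls_sd,bmd_tblh_mean,bmd_tblh_sd
M,5.0,6.0,1.8,13.0,1.82,700.0,105.0,0.78,0.0546,0.55,0.0495,0.62,0.0496
M,5.5,6.2567,1.877,13.7336,1.9227,744.0138,111.6021,0.7888,0.0552,0.5621,0.0506,0.6321,0.0506
M,6.0,6.5329,1.9599,14.5225,2.0331,791.3495,118.7024,0.7983,0.0559,0.5751,0.0518,0.6451,0.0516
M,6.5,6.8284,2.0485,15.3668,2.1513,842.0069,126.301,0.8084,0.0566,0.5891,0.053,0.6591,0.0527
M,7.0,7.1433,2.143,16.2664,2.2773,895.9862,134.3979,0.8192,0.0573,0.6039,0.0544,0.6739,0.0539
M,7.5,7.4775,2.2433,17.2215,2.411,953.2872,142.9931,0.8307,0.0581,0.6197,0.0558,0.6897,0.0552
M,8.0,7.8311,2.3493,18.2318,2.5525,1013.91,152.0865,0.8428,0.059,0.6363,0.0573,0.7063,0.0565
M,8.5,8.2042,2.4612,19.2976,2.7017,1077.8547,161.6782,0.8556,0.0599,0.6539,0.0589,0.7239,0.0579
M,9.0,8.5965,2.579,20.4187,2.8586,1145.1211,171.7682,0.869,0.0608,0.6724,0.0605,0.7424,0.0594
M,9.5,9.0083,2.7025,21.5952,3.0233,1215.7093,182.3564,0.8831,0.0618,0.6918,0.0623,0.7618,0.0609
M,10.0,9.4394,2.8318,22.827,3.1958,1289.6194,193.4429,0.8979,0.0629,0.7121,0.0641,0.7821,0.0626
M,10.5,9.89,2.967,24.1142,3.376,1366.8512,205.0277,0.9134,0.0639,0.7334,0.066,0.8034,0.0643
M,11.0,10.3599,3.108,25.4567,3.5639,1447.4048,217.1107,0.9295,0.0651,0.7555,0.068,0.8255,0.066
M,11.5,10.8491,3.2547,26.8547,3.7597,1531.2803,229.692,0.9463,0.0662,0.7786,0.0701,0.8486,0.0679
M,12.0,11.3578,3.4073,28.308,3.9631,1618.4775,242.7716,0.9637,0.0675,0.8026,0.0722,0.8726,0.0698
M,12.5,11.8858,3.5657,29.8166,4.1743,1708.9965,256.3495,0.9818,0.0687,0.8275,0.0745,0.8975,0.0718
M,13.0,12.4332,3.73,31.3806,4.3933,1802.8374,270.4256,1.0006,0.07,0.8533,0.0768,0.9233,0.0739
M,13.5,13.0,3.9,33.0,4.62,1900.0,285.0,1.02,0.0714,0.88,0.0792,0.95,0.076
F,5.0,6.48,1.944,11.7,1.638,665.0,99.75,0.7644,0.0535,0.55,0.0495,0.6014,0.0481
F,5.5,6.7573,2.0272,12.3602,1.7304,706.8131,106.022,0.773,0.0541,0.5621,0.0506,0.6131,0.0491
F,6.0,7.0555,2.1167,13.0702,1.8298,751.782,112.7673,0.7823,0.0548,0.5751,0.0518,0.6258,0.0501
F,6.5,7.3746,2.2124,13.8301,1.9362,799.9066,119.986,0.7922,0.0555,0.5891,0.053,0.6393,0.0511
F,7.0,7.7147,2.3144,14.6398,2.0496,851.1869,127.678,0.8028,0.0562,0.6039,0.0544,0.6537,0.0523
F,7.5,8.0757,2.4227,15.4993,2.1699,905.6228,135.8434,0.814,0.057,0.6197,0.0558,0.669,0.0535
F,8.0,8.4576,2.5373,16.4087,2.2972,963.2145,144.4822,0.8259,0.0578,0.6363,0.0573,0.6851,0.0548
F,8.5,8.8605,2.6581,17.3678,2.4315,1023.9619,153.5943,0.8385,0.0587,0.6539,0.0589,0.7022,0.0562
F,9.0,9.2843,2.7853,18.3768,2.5728,1087.8651,163.1798,0.8516,0.0596,0.6724,0.0605,0.7201,0.0576
F,9.5,9.729,2.9187,19.4356,2.721,1154.9239,173.2386,0.8655,0.0606,0.6918,0.0623,0.739,0.0591
F,10.0,10.1946,3.0584,20.5443,2.8762,1225.1384,183.7708,0.88,0.0616,0.7121,0.0641,0.7587,0.0607
F,10.5,10.6812,3.2043,21.7028,3.0384,1298.5087,194.7763,0.8951,0.0627,0.7334,0.066,0.7793,0.0623
F,11.0,11.1887,3.3566,22.9111,3.2076,1375.0346,206.2552,0.9109,0.0638,0.7555,0.068,0.8008,0.0641
F,11.5,11.7171,3.5151,24.1692,3.3837,1454.7163,218.2074,0.9273,0.0649,0.7786,0.0701,0.8231,0.0659
F,12.0,12.2664,3.6799,25.4772,3.5668,1537.5536,230.633,0.9444,0.0661,0.8026,0.0722,0.8464,0.0677
F,12.5,12.8367,3.851,26.8349,3.7569,1623.5467,243.532,0.9622,0.0674,0.8275,0.0745,0.8705,0.0696
F,13.0,13.4279,4.0284,28.2426,3.954,1712.6955,256.9043,0.9806,0.0686,0.8533,0.0768,0.8956,0.0716
F,13.5,14.04,4.212,29.7,4.158,1805.0,270.75,0.9996,0.07,0.88,0.0792,0.9215,0.0737
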