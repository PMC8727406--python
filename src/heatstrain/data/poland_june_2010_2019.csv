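period,tmrel_pct,shrmrel_pct,utci_mean,heat_stress_days,o3_ugm3,o3_pct,pm25_ugm3,pm25_pct
2010,101.7,115.6,20.0,1.3,61.3,94.9,13.3,108.5
2011,,45.2,20.5,0.5,67.9,105.2,12.5,102.3
2012,99.5,88.2,17.8,1.0,65.1,100.8,11.9,97.5
2013,98.5,97.4,20.1,1.4,59.9,92.7,13.6,110.9
2014,,110.9,18.2,0.9,59.4,91.9,11.6,95.2
2015,99.9,89.6,19.4,0.9,66.9,103.6,11.7,95.9
2016,98.6,201.5,22.2,2.5,66.1,102.3,12.1,98.7
2017,99.9,34.8,19.7,0.3,64.8,100.3,11.1,90.8
2018,101.9,116.9,21.6,1.0,69.9,108.2,12.2,100.1
ref_mean,100.0,100.0,20.0,1.1,64.6,100.0,12.2,100.0
2019,109.6,509.6,26.8,6.7,76.6,118.6,12.3,100.8
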