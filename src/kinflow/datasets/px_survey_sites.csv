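population,site,latitude,longitude,sample_size,date,time_code
FJ1,Fujian,25.94392,119.25313,32,2016-05-12,1
FL1,the Philippines,15.10136,120.58555,32,2016-06-21,1
GD1,Guangdong,23.16017,113.35634,31,2016-06-16,1
GX1,Guangxi,22.85021,108.2448,32,2016-06-03,1
GZ1,Guizhou,26.61723,106.66834,32,2016-06-28,1
HN1,Hainan,18.29119,109.59779,32,2016-04-28,1
JX1,Jiangxi,28.76363,115.83489,32,2016-04-24,1
MY1,Myanmar,16.90561,96.24384,32,2016-07-09,1
TW1,Taiwan,23.77326,120.45462,32,2016-06-10,1
VN1,Vietnam,21.04872,105.85288,29,2016-07-07,1
XX1,Hunan,28.1974,113.07853,25,2016-07-07,1
YN1,Yunnan,24.78023,102.79866,32,2016-06-25,1
FJ2,Fujian,25.94392,119.25313,20,2016-12-06,2
FL2,the Philippines,15.10136,120.58555,32,2017-01-16,2
GD2,Guangdong,23.16017,113.35634,32,2017-01-09,2
GX2,Guangxi,22.85021,108.2448,32,2017-12-18,2
GZ2,Guizhou,26.61723,106.66834,32,2016-12-23,2
HN2,Hainan,18.29119,109.59779,32,2017-01-06,2
JX2,Jiangxi,28.76363,115.83489,29,2016-10-25,2
MY2,Myanmar,16.90561,96.24384,32,2016-12-22,2
TW2,Taiwan,22.64479,120.4785,29,2016-10-22,2
VN2,Vietnam,21.04872,105.85288,32,2016-12-18,2
XX2,Hunan,27.81154,113.06472,32,2016-12-20,2
FJ3,Fujian,25.94392,119.25313,32,2017-04-27,3
FL3,the Philippines,15.10136,120.58555,32,2017-05-06,3
GD3,Guangdong,23.16017,113.35634,32,2017-05-23,3
GX3,Guangxi,21.68073,109.17835,32,2017-04-29,3
GZ3,Guizhou,26.61723,106.66834,32,2017-06-06,3
HN3,Hainan,20.03826,110.17471,5,2017-05-15,3
JX3,Jiangxi,28.76363,115.83489,32,2017-05-17,3
MY3,Myanmar,16.90561,96.24384,32,2017-06-04,3
TW3,Taiwan,22.59524,120.60754,32,2017-05-24,3
VN3,Vietnam,21.04872,105.85288,21,2017-06-01,3
XX3,Hunan,27.81154,113.06472,32,2017-05-25,3
YN3,Yunnan,24.78023,102.79866,32,2017-06-05,3
YC3,Yunnan,24.87667,102.78666,14,2017-05-22,3
FJ4,Fujian,25.94392,119.25313,32,2017-11-07,4
FL4,the Philippines,15.10136,120.58555,32,2017-11-20,4
GD4,Guangdong,23.16017,113.35634,32,2017-11-25,4
GB4,Guizhou,26.61831,106.66114,32,2017-12-02,4
GL4,Guizhou,26.61723,106.66834,32,2017-12-01,4
HN4,Hainan,18.29119,109.59779,32,2018-01-26,4
JX4,Jiangxi,28.76363,115.83489,32,2017-12-15,4
JX5,Jiangxi,28.76363,115.83489,6,2018-01-06,4
MY4,Myanmar,16.90561,96.24384,32,2017-11-28,4
TW4,Taiwan,24.80418,120.94269,32,2018-01-26,4
VN4,Vietnam,21.04872,105.85288,32,2017-11-26,4
YN4,Yunnan,24.78023,102.79866,32,2017-11-29,4
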