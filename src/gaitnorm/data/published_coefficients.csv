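joint,keypoint_id,parameter,beta0,beta_speed,beta_age,beta_sex,beta_bmi,rmse,n_predictors,is_constant
hip,HIS1,timing,1,NS,NS,NS,NS,0,0,true
hip,HIS1,angle,9.1713,20.4474,-0.0393,-4.8000,0.4698,5.48,4,false
hip,HIS2,timing,37.0166,-10.9165,NS,-0.2067,NS,1.28,2,false
hip,HIS2,angle,-5.7088,7.0238,-0.0345,-4.7659,0.3042,5.75,4,false
hip,HIS3,timing,58.4489,-14.7747,NS,0.7288,0.0829,2.18,3,false
hip,HIS3,angle,-11.9470,-17.0960,-0.0655,-6.4275,0.4643,5.56,4,false
hip,HIS4,timing,73.4992,-21.8230,NS,-0.4234,NS,2.49,2,false
hip,HIS4,angle,2.7327,-29.6207,-0.0383,-5.9665,0.3500,5.93,4,false
hip,HIS5,timing,90.0414,-3.1646,NS,1.0861,NS,2.58,2,false
hip,HIS5,angle,17.7667,13.8347,-0.0619,-5.4664,0.2803,5.10,4,false
hip,HIS6,timing,101,NS,NS,NS,NS,0,0,true
hip,HIS6,angle,9.1713,20.4474,-0.0393,-4.8000,0.4698,5.48,4,false
knee,KNS1,timing,1,NS,NS,NS,NS,0,0,true
knee,KNS1,angle,-4.8743,1.4053,0.0702,-1.3015,NS,4.22,3,false
knee,KNS2,timing,12.0826,6.6111,-0.0234,NS,NS,2.36,2,false
knee,KNS2,angle,-8.6072,31.3556,0.1093,NS,0.1168,4.96,3,false
knee,KNS3,timing,34.9333,4.5361,0.0395,1.2407,NS,3.74,3,false
knee,KNS3,angle,-3.1995,-2.5919,0.0183,-1.2237,0.1868,4.13,4,false
knee,KNS4,timing,56.0112,-16.3459,NS,-0.3331,NS,1.89,2,false
knee,KNS4,angle,5.0083,-5.4871,NS,-2.3842,0.1132,3.91,3,false
knee,KNS5,timing,73.4992,-21.8230,NS,-0.4234,NS,2.49,2,false
knee,KNS5,angle,35.5374,-12.2774,0.0301,-2.5634,0.1980,5.87,4,false
knee,KNS6,timing,77.0733,-7.4887,NS,-0.5444,NS,2.03,2,false
knee,KNS6,angle,41.6388,21.6639,NS,-1.7741,0.1663,4.99,3,false
knee,KNS7,timing,94.2815,-5.5495,NS,-0.0796,NS,0.69,2,false
knee,KNS7,angle,3.4933,16.9053,NS,NS,-0.1651,5.98,2,false
knee,KNS8,timing,101,NS,NS,NS,NS,0,0,true
knee,KNS8,angle,-4.8743,1.4053,0.0702,-1.3015,NS,4.22,3,false
ankle,ANS1,timing,1,NS,NS,NS,NS,0,0,true
ankle,ANS1,angle,-1.2223,NS,NS,1.0414,NS,2.96,1,false
ankle,ANS2,timing,7.2097,NS,NS,NS,NS,2.24,0,false
ankle,ANS2,angle,-4.6017,4.0205,NS,0.7755,-0.0965,2.92,3,false
ankle,ANS3,timing,37.0166,-10.9165,NS,-0.2067,NS,1.28,2,false
ankle,ANS3,angle,7.0096,1.0447,-0.0086,NS,0.0789,2.54,3,false
ankle,ANS4,timing,51.8442,-14.3710,0.0580,NS,NS,2.66,2,false
ankle,ANS4,angle,13.4480,-2.3965,0.0298,-0.4831,0.0765,2.91,4,false
ankle,ANS5,timing,72.0845,-15.6556,0.0197,-0.2129,NS,1.99,3,false
ankle,ANS5,angle,-9.3038,-15.5580,NS,1.4280,NS,6.31,2,false
ankle,ANS6,timing,84.7634,NS,0.0160,0.7208,-0.0472,3.40,3,false
ankle,ANS6,angle,7.4315,-2.8563,-0.0330,NS,NS,2.91,2,false
ankle,ANS7,timing,101,NS,NS,NS,NS,0,0,true
ankle,ANS7,angle,-1.2223,NS,NS,1.0414,NS,2.96,1,false
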