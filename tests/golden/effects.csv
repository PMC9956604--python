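feature,estimate,p,note,q
APOE,0,1,,1
age,0,1,,1
education,0,1,,1
sex,,,non-numeric,
CD33,-3.169925001,5.322298435e-104,,9.580137183e-103
M1_g0,-2.198456499,1.976900117e-66,,8.896050525e-66
M1_g1,-2.362647297,1.595954835e-67,,9.575729009e-67
M1_g2,-2.300614762,1.334730663e-68,,1.201257596e-67
M1_g3,-2.345496192,3.181085322e-66,,1.145190716e-65
M2_g0,-1.43886113,3.189641279e-40,,5.219413001e-40
M2_g1,-1.419826776,2.610726137e-40,,4.699307046e-40
M2_g2,-1.472298297,1.237046342e-41,,2.474092684e-41
M3_g0,-1.663620929,7.395839106e-50,,1.901787199e-49
M3_g1,-1.73958073,2.558756564e-51,,7.676269691e-51
M3_g2,-1.637489995,1.236514958e-49,,2.782158655e-49
M4_g0,-0.7666518732,8.339226248e-12,,1.154662096e-11
M4_g1,-0.8069834618,5.434447738e-13,,8.151671607e-13
MMSE,4.48,3.770024332e-06,,4.524029198e-06
Braak,-0.965,4.654089971e-07,,5.983829963e-07
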