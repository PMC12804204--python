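sex,age_band,edu_level,n_2002,n_2008,p_healthy_2002,p_healthy_2008,mean_opinion_healthy,mean_opinion_unhealthy,p_habit,p_budget
male,15-29,low,52,148,0.019,0.027,0.63,0.54,0.53,0.54
male,15-29,middle,97,223,0.031,0.049,0.51,0.55,0.58,0.56
male,15-29,high,84,137,0.036,0.073,0.80,0.56,0.65,0.61
male,30-59,low,241,355,0.050,0.082,0.64,0.53,0.64,0.57
male,30-59,middle,122,225,0.074,0.111,0.61,0.57,0.84,0.48
male,30-59,high,118,180,0.059,0.167,0.74,0.59,0.83,0.43
male,60-75,low,95,149,0.147,0.174,0.60,0.57,0.58,0.53
male,60-75,middle,31,46,0.032,0.239,0.63,0.57,0.86,0.47
male,60-75,high,28,34,0.179,0.206,0.62,0.52,0.93,0.29
female,15-29,low,66,110,0.030,0.036,0.54,0.56,0.72,0.73
female,15-29,middle,121,252,0.050,0.087,0.70,0.59,0.76,0.63
female,15-29,high,100,195,0.070,0.077,0.66,0.61,0.81,0.70
female,30-59,low,341,369,0.135,0.106,0.68,0.60,0.77,0.69
female,30-59,middle,178,302,0.146,0.119,0.73,0.61,0.85,0.66
female,30-59,high,124,211,0.145,0.171,0.69,0.64,0.89,0.59
female,60-75,low,235,241,0.200,0.220,0.64,0.63,0.71,0.72
female,60-75,middle,46,87,0.261,0.310,0.68,0.64,0.81,0.69
female,60-75,high,17,40,0.235,0.300,0.70,0.62,0.82,0.61
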