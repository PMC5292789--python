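id,name,mean_utility_study1,sd_utility_study1,mean_utility_study2,sd_utility_study2,dw2010,dw2013
1,"Fractures, treated (long term)",0.667,0.131,0.694,0.130,0.003,0.005
2,"Distance vision, mild",,,0.826,0.154,0.004,0.003
5,"Anemia, mild",,,0.813,0.138,0.005,0.004
8,"Amputation of toe",,,0.650,0.127,0.008,0.006
11,"Asthma, controlled",,,0.809,0.128,0.009,0.015
22,"Claudication",,,0.644,0.177,0.016,0.014
29,"Stroke, long term mild",,,0.550,0.168,0.021,0.019
37,"Disfigurement, level 1 with itch or pain",,,0.639,0.177,0.029,0.027
47,"Fracture of foot bones (long term, without treatment)",,,0.615,0.151,0.033,0.026
55,"Headache tension type",0.530,0.169,0.350,0.204,0.040,0.037
60,"Amputation of both legs (long-term with treatment)",,,0.304,0.244,0.051,0.088
77,"Injured nerves (short term)",,,0.553,0.193,0.065,0.100
96,"Fracture tibia, patella (short term)",,,0.389,0.170,0.087,0.050
107,"Musculoskeletal problems (arms moderate)",,,0.474,0.173,0.114,0.117
111,"Severe wasting",0.474,0.204,0.486,0.263,0.127,0.128
149,"Crohn's disease",,,0.455,0.200,0.225,0.231
155,"Parkinson's disease moderate",,,0.391,0.201,0.263,0.267
161,"Gout, acute",,,0.193,0.212,0.293,0.295
174,"Severe chest injury (short term, with or without treatment)",,,0.331,0.201,0.352,0.369
186,"Fracture of pelvis short term",,,0.106,0.203,0.390,0.279
193,"Headache (migraine)",,,0.548,0.194,0.433,0.441
200,"Rectovaginal fistula",,,0.449,0.217,0.492,0.501
203,"Terminal phase, without medication (for cancers, end-stage kidney/liver disease)",,,0.317,0.225,0.519,0.569
206,"AIDS cases (not received ARV treatment)",,,0.360,0.228,0.547,0.582
214,"Traumatic brain injury (long-term consequences)",,,0.200,0.257,0.625,0.637
219,"Multiple sclerosis (severe)",,,0.144,0.198,0.707,0.719
220,"Schizophrenia, acute",0.289,0.203,0.341,0.192,0.756,0.778
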