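sex,cancer_type,horizon_years,std_aic,std_bic,std_pp,group1_aic,group1_bic,group2_aic,group2_bic,group3_aic,group3_bic,group4_aic,group4_bic,group5_aic,group5_bic,age55_aic,age55_bic,age65_aic,age65_bic,age75_aic,age75_bic,age85_aic,age85_bic
female,bladder,1,0.04,0.37,0.39,0.05,0.64,0.05,0.49,0.04,0.23,0.04,0.16,0.04,0.46,0.04,0.34,0.04,0.17,0.03,0.19,0.03,0.50
female,bladder,5,-0.01,-0.24,0.54,0.00,-0.61,0.00,-0.43,0.00,-0.10,0.00,0.05,-0.02,-0.35,0.00,-0.25,0.00,0.00,0.00,0.05,-0.02,-0.42
female,lung,1,-0.24,-0.26,-0.05,-0.47,-0.47,-0.38,-0.38,-0.19,-0.19,-0.15,-0.16,-0.30,-0.33,-0.28,-0.28,-0.14,-0.14,-0.20,-0.22,-0.35,-0.38
female,lung,5,0.06,0.07,0.22,0.10,0.09,0.05,0.04,-0.04,-0.05,-0.02,-0.02,0.16,0.18,-0.01,-0.01,-0.06,-0.06,0.05,0.06,0.22,0.24
female,colon,1,-0.07,0.08,0.22,-0.23,0.24,-0.38,0.12,-0.46,0.01,-0.30,0.00,0.21,0.12,-0.45,0.06,-0.44,-0.01,-0.07,0.05,0.34,0.16
female,colon,5,0.11,-0.08,0.40,0.08,-0.05,0.07,-0.03,0.05,-0.03,0.03,-0.06,0.18,-0.11,0.06,-0.03,0.04,-0.04,0.02,-0.09,0.23,-0.13
female,rectum,1,0.03,-0.08,0.13,0.20,0.14,0.09,0.04,0.00,-0.04,-0.04,-0.12,0.07,-0.12,0.04,-0.01,-0.03,-0.08,-0.05,-0.15,0.09,-0.12
female,rectum,5,-0.09,-0.14,0.09,0.01,-0.07,-0.04,-0.11,-0.02,-0.08,0.11,0.07,-0.27,-0.30,-0.05,-0.11,0.03,-0.02,0.18,0.14,-0.45,-0.48
female,breast,1,-0.16,-0.17,-0.08,-0.08,-0.06,-0.05,-0.06,-0.02,-0.07,-0.30,-0.13,-0.33,-0.44,0.05,-0.06,-0.23,-0.09,-0.17,-0.20,-0.18,-0.50
female,breast,5,0.03,0.05,0.22,0.01,0.03,-0.10,0.03,0.45,0.02,-0.75,0.04,0.44,0.11,0.74,0.02,-0.62,0.03,0.17,0.05,0.99,0.13
female,stomach,1,-0.10,0.03,-0.02,-2.43,-0.27,-1.63,-0.17,-0.84,-0.11,-0.17,-0.14,0.38,0.17,-1.21,-0.13,-0.49,-0.10,0.11,-0.18,0.48,0.23
female,stomach,5,0.20,-0.11,0.55,0.89,-0.13,0.56,-0.13,0.22,-0.07,-0.01,0.08,0.20,-0.20,0.38,-0.11,0.09,-0.02,-0.06,0.16,0.36,-0.40
female,melanoma,1,-0.01,-0.01,0.11,0.00,0.00,-0.01,-0.01,0.03,0.03,0.06,0.06,-0.09,-0.09,0.01,0.01,0.05,0.05,0.06,0.06,-0.13,-0.13
female,melanoma,5,0.00,0.00,0.15,0.02,0.02,0.03,0.03,0.04,0.04,0.03,0.03,-0.08,-0.08,0.03,0.03,0.04,0.04,0.01,0.01,-0.10,-0.10
female,ovarian,1,-0.19,-0.13,0.04,0.36,0.06,0.03,0.00,-0.25,-0.13,-0.61,-0.28,-0.10,-0.16,-0.15,-0.05,-0.35,-0.21,-1.02,-0.32,0.47,-0.06
female,ovarian,5,0.18,0.06,0.35,0.28,0.01,-1.25,0.08,0.90,0.17,0.69,0.19,-0.16,-0.13,-0.82,0.12,2.15,0.21,-1.71,0.10,1.11,-0.26
female,hodgkin,1,-0.10,-0.10,0.28,-0.02,-0.02,-0.04,-0.04,-0.10,-0.10,-0.19,-0.19,-0.34,-0.34,-0.07,-0.07,-0.14,-0.14,-0.26,-0.26,-0.39,-0.39
female,hodgkin,5,-0.01,-0.01,0.01,-0.01,-0.01,-0.01,-0.01,-0.02,-0.02,-0.02,-0.02,0.00,0.00,-0.02,-0.02,-0.02,-0.02,-0.01,-0.01,0.00,0.00
male,bladder,1,-0.14,0.02,0.29,-0.13,0.33,-0.13,0.30,-0.12,0.18,-0.12,0.00,-0.17,-0.05,-0.12,0.26,-0.12,0.11,-0.13,-0.11,-0.18,-0.04
male,bladder,5,-0.02,-0.35,0.23,0.04,0.01,0.04,-0.01,0.03,-0.06,0.02,0.09,-0.06,-0.73,0.04,-0.04,0.02,-0.03,0.00,0.25,-0.09,-1.25
male,lung,1,-0.25,-0.15,-0.11,-2.30,-0.13,-1.08,-0.10,0.74,-0.03,-0.82,-0.05,-0.10,-0.28,0.35,-0.06,-0.10,-0.02,0.07,-0.13,-0.45,-0.39
male,lung,5,0.08,0.06,0.25,-1.57,0.06,-0.49,0.03,0.80,-0.03,-0.58,-0.03,0.38,0.17,0.69,0.00,-0.07,-0.04,0.30,0.01,0.30,0.28
male,colon,1,-0.09,-0.07,0.25,-0.74,0.24,0.44,0.07,0.27,-0.07,-0.45,-0.08,0.00,-0.10,0.83,-0.01,-0.71,-0.10,1.06,-0.04,-1.09,-0.14
male,colon,5,0.03,0.00,0.33,-2.69,-0.01,1.53,0.04,1.10,0.05,-1.09,-0.03,0.38,0.00,2.83,0.06,-1.81,0.03,2.88,-0.10,-1.74,0.08
male,rectum,1,-0.05,-0.04,0.09,-0.28,1.13,0.09,0.50,0.17,-0.09,-0.44,-0.20,0.18,-0.06,0.25,0.17,-0.08,-0.24,-0.32,-0.10,0.42,-0.05
male,rectum,5,-0.02,-0.10,0.25,-2.70,-0.32,1.01,-0.19,0.44,-0.06,-0.51,0.00,0.11,-0.18,2.17,-0.12,-1.94,-0.01,1.46,-0.01,-0.36,-0.32
male,stomach,1,0.05,0.13,0.62,-1.07,-0.03,-0.81,-0.01,-0.41,0.01,0.08,-0.03,0.35,0.29,-0.63,0.01,-0.19,0.00,0.34,-0.04,0.31,0.52
male,stomach,5,0.07,-0.08,0.29,0.19,0.09,0.18,0.02,0.14,-0.01,0.05,0.08,0.05,-0.21,0.17,-0.01,0.11,0.01,-0.01,0.12,0.11,-0.49
male,melanoma,1,-0.01,-0.05,0.17,-0.01,-0.07,-0.17,-0.03,0.31,0.05,-0.02,0.11,-0.17,-0.27,0.12,0.00,0.23,0.09,-0.22,0.08,-0.17,-0.44
male,melanoma,5,-0.13,-0.15,0.00,-0.02,-0.03,-0.26,-0.05,0.41,-0.02,-0.21,-0.02,-0.48,-0.50,0.19,-0.04,0.12,0.00,-0.13,-0.09,-0.71,-0.74
male,prostate,1,-0.20,-0.19,-0.10,-0.10,-0.07,-0.04,-0.04,-0.09,-0.06,-0.21,-0.24,-1.17,-1.04,-0.07,-0.06,-0.04,-0.04,-0.16,-0.11,-0.55,-0.65
male,prostate,5,-0.01,0.01,0.08,-0.36,-0.02,0.24,0.00,-0.40,0.00,0.46,0.00,-0.28,0.12,-0.01,-0.01,0.08,0.00,-0.41,-0.01,0.98,0.06
male,hodgkin,1,0.13,0.13,0.27,0.01,0.01,0.06,0.06,0.16,0.16,0.32,0.32,0.52,0.52,0.10,0.10,0.24,0.24,0.44,0.44,0.59,0.59
male,hodgkin,5,0.00,0.00,0.24,0.00,0.00,0.00,0.00,0.01,0.01,0.01,0.01,-0.01,-0.01,0.01,0.01,0.01,0.01,0.00,0.00,-0.02,-0.02
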