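site_id,location_name,min,max,mean,std
S1,Nadrai Gate,0.50,0.70,0.58,0.08
S2,Madhopuri Colony,1.32,1.48,1.40,0.06
S3,Maharana Pratap Colony,1.72,1.90,1.80,0.06
S4,PWD Colony,1.65,1.90,1.80,0.09
S5,Officer Colony,1.70,1.88,1.80,0.07
S6,Sahawar Gate,1.88,2.80,2.40,0.35
S7,Railway Road,1.65,1.90,1.80,0.09
S8,Ahrauli,2.40,2.90,2.60,0.23
S9,Arya Nagar,1.80,3.10,2.50,0.54
S10,Amapur Road,2.30,3.10,2.78,0.29
S11,Jakharrudder pur,2.30,2.80,2.50,0.21
S12,Awas Vikas Colony,1.10,2.80,2.24,0.72
S13,Tarora,2.90,3.90,3.40,0.37
S14,Bilram Gate,1.60,3.00,2.42,0.51
S15,Durga Colony,3.60,4.00,3.80,0.16
S16,Yadav Nagar,2.20,3.10,2.65,0.38
S17,Jay Jay Ram Mohalla,2.50,2.80,2.66,0.11
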