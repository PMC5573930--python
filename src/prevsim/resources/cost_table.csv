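condition,annual_cost,event_cost,utility_decrement,absence_days_per_year
diabetes,300,0,0.024,3
cvd,200,4000,0.06,5
chf,1000,2500,0.10,8
foot_ulcer,500,1500,0.06,4
amputation,800,10000,0.12,10
blindness,500,2000,0.07,6
renal_failure,25000,5000,0.17,15
osteoarthritis,200,2000,0.09,6
depression,400,0,0.14,12
breast_cancer,1000,12000,0.08,20
colon_cancer,1000,15000,0.08,20
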