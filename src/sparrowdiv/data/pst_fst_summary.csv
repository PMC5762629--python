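trait,P_ST,ci_low,ci_high,critical_c_h2,verdict,fst_upper_ci
Body mass,0.313,0.176,0.539,0.079,P_ST >> F_ST,0.016
Wing length,0.253,0.109,0.445,0.131,P_ST > F_ST,0.016
Tarsus length,0.443,0.292,0.68,0.046,P_ST >> F_ST,0.016
Bill length,0.13,0.054,0.296,0.171,P_ST > F_ST,0.016
Bill width,0.0,0.0,0.118,,P_ST = F_ST,0.016
Right cheek brightness,0.113,0.025,0.288,0.959,P_ST > F_ST,0.024
Left cheek brightness,0.13,0.009,0.352,,P_ST = F_ST,0.024
Belly brightness,0.379,0.204,0.662,0.124,P_ST >> F_ST,0.024
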