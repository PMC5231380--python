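conflict_class,district,mmr_1982,mmr_end,cf_end,rate_pre,rate_conflict,endpoint_year,label,na_fields
HIGH,Batticaloa,1.30,0.04,0.50,-0.054,-0.028,1999,"Rate is worse; outcome is better",
HIGH,Jaffna,0.10,0.40,0.01,-0.107,-0.012,2002,Rate and outcome are worse,
HIGH,Kilinochchi,,1.43,,,,1999,Unable to determine,mmr_1982;cf_end;rate_pre;rate_conflict
HIGH,Mannar,0.90,0.63,0.45,-0.014,0.069,1999,"Rate is better; outcome is worse",
HIGH,Mullaitivu,,0.21,,,,1999,Unable to determine,mmr_1982;cf_end;rate_pre;rate_conflict
HIGH,Trincomalee,0.70,,0.37,-0.032,-0.025,1999,Rate is worse,mmr_end
HIGH,Vavuniya,0.30,0.60,0.06,-0.107,-0.010,1999,"Rate is worse; outcome is same",
INTERMITTENT,Ampara,0.60,0.17,0.12,-0.077,-0.046,2002,Rate and outcome are worse,
INTERMITTENT,Anuradhapura,0.20,0.19,0.02,-0.119,-0.036,2002,Rate and outcome are worse,
INTERMITTENT,Polonnaruwa,0.40,0.14,0.07,-0.086,-0.047,2002,Rate and outcome are worse,
INTERMITTENT,Puttalam,0.30,0.21,0.03,-0.107,-0.043,2002,Rate and outcome are worse,
NONE,Badulla,0.80,0.28,0.27,-0.061,-0.023,2002,Rate and outcome are worse,
NONE,Colombo,0.50,0.12,0.08,-0.088,-0.038,2002,Rate and outcome are worse,
NONE,Galle,0.60,0.11,0.23,-0.047,-0.042,2002,"Rate is worse; outcome is better",
NONE,Gampaha,0.30,0.12,,,-0.022,2002,Unable to determine,cf_end;rate_pre
NONE,Hambantota,0.80,0.15,0.05,-0.102,-0.033,2002,Rate and outcome are worse,
NONE,Kandy,0.80,0.10,0.18,-0.071,-0.042,2002,"Rate is worse; outcome is better",
NONE,Kaluthara,0.50,0.06,0.11,-0.071,-0.042,2002,"Rate is worse; outcome is better",
NONE,Kegalle,0.60,0.12,0.13,-0.086,-0.040,1999,"Rate is worse; outcome is better",
NONE,Kurunegala,0.60,0.20,0.23,-0.048,-0.035,2002,"Rate is worse; outcome is better",
NONE,Matale,1.00,0.12,0.80,-0.013,-0.043,1999,Rate and outcome are better,
NONE,Matara,0.90,0.14,0.53,-0.026,-0.043,2002,Rate and outcome are better,
NONE,Moneragala,0.60,0.15,0.16,-0.065,-0.045,2002,"Rate is worse; outcome is better",
NONE,Nuwara Eliya,1.20,0.52,0.37,-0.057,-0.025,2002,Rate and outcome are worse,
NONE,Ratnapura,0.70,0.31,0.11,-0.087,-0.035,2002,Rate and outcome are worse,
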