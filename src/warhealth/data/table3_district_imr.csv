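conflict_class,district,imr_1982,imr_2002,cf_2002,rate_pre,rate_conflict,na_fields
HIGH,Batticaloa,27,15.2,6.2,-0.066,-0.019,
HIGH,Jaffna,17,6,12.7,-0.027,-0.038,
HIGH,Kilinochchi,,3.9,,,,imr_1982;cf_2002;rate_pre;rate_conflict
HIGH,Mannar,27,6.9,13.1,-0.010,-0.030,
HIGH,Mullaitivu,,8.9,,,,imr_1982;cf_2002;rate_pre;rate_conflict
HIGH,Trincomalee,18,2.5,4.1,-0.060,-0.043,
HIGH,Vavuniya,16,11.8,4.8,-0.058,-0.016,
INTERMITTENT,Ampara,20,7,3.5,-0.076,-0.031,
INTERMITTENT,Anuradhapura,26,17.6,11.6,-0.034,-0.012,
INTERMITTENT,Polonnaruwa,14,16.1,1.7,-0.086,0.031,
INTERMITTENT,Puttalam,24,6.3,13.5,-0.032,-0.040,
NONE,Badulla,34,15.9,10.7,-0.056,-0.025,
NONE,Colombo,50,16.2,,,,cf_2002;rate_pre
NONE,Galle,34,10.9,13.3,-0.046,-0.032,
NONE,Gampaha,22,5.2,,,-0.037,cf_2002;rate_pre
NONE,Hambantota,18,4.7,4.7,-0.065,-0.035,
NONE,Kaluthara,20,4,3.6,-0.082,-0.043,
NONE,Kandy,39,15.8,12.1,-0.065,-0.035,
NONE,Kegalle,29,9.2,7.4,-0.066,-0.035,
NONE,Kurunegala,29,10.8,14.4,-0.031,-0.032,
NONE,Matale,29,7.6,6.3,-0.058,-0.006,
NONE,Matara,33,5.9,18.7,-0.028,-0.042,
NONE,Moneragala,13,2,2.6,-0.076,-0.045,
NONE,Nuwara Eliya,49,16,16.1,-0.054,-0.036,
NONE,Ratnapura,43,13.5,17.6,-0.044,-0.033,
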