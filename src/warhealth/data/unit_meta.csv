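unit_id,conflict_class,creation_year,imr_endpoint_year,mmr_endpoint_year
Ampara,INTERMITTENT,,2002,2002
Anuradhapura,INTERMITTENT,,2002,2002
Badulla,NONE,,2002,2002
Batticaloa,HIGH,,2002,1999
Colombo,NONE,,2002,2002
Galle,NONE,,2002,2002
Gampaha,NONE,,2002,2002
Hambantota,NONE,,2002,2002
Jaffna,HIGH,,2002,2002
Kaluthara,NONE,,2002,2002
Kandy,NONE,,2002,2002
Kegalle,NONE,,2002,1999
Kilinochchi,HIGH,1984,2002,1999
Kurunegala,NONE,,2002,2002
Mannar,HIGH,,2002,1999
Matale,NONE,,2002,1999
Matara,NONE,,2002,2002
Moneragala,NONE,,2002,2002
Mullaitivu,HIGH,1978,2002,1999
Nuwara Eliya,NONE,,2002,2002
Polonnaruwa,INTERMITTENT,,2002,2002
Puttalam,INTERMITTENT,,2002,2002
Ratnapura,NONE,,2002,2002
Trincomalee,HIGH,,2002,1999
Vavuniya,HIGH,,2002,1999
NATIONAL,NATIONAL,,2002,2002
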