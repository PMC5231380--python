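conflict_class,district,label,endpoint_1999
HIGH,Batticaloa,"Rate is worse; MMR is better",true
HIGH,Jaffna,Rate and MMR are worse,false
HIGH,Kilinochchi,Unable to determine,false
HIGH,Mannar,"Rate is better; MMR is worse",true
HIGH,Mullaitivu,Unable to determine,false
HIGH,Trincomalee,Rate is worse,true
HIGH,Vavuniya,"Rate is worse; MMR is same",true
INTERMITTENT,Ampara,Rate and MMR are worse,false
INTERMITTENT,Anuradhapura,Rate and MMR are worse,false
INTERMITTENT,Polonnaruwa,Rate and MMR are worse,false
INTERMITTENT,Puttalam,Rate and MMR are worse,false
NONE,Badulla,Rate and MMR are worse,false
NONE,Colombo,Rate and MMR are worse,false
NONE,Galle,"Rate is worse; MMR is better",false
NONE,Gampaha,Unable to determine,false
NONE,Hambantota,Rate and MMR are worse,false
NONE,Kandy,"Rate is worse; MMR is better",false
NONE,Kaluthara,"Rate is worse; MMR is better",false
NONE,Kegalle,"Rate is worse; MMR is better",true
NONE,Kurunegala,"Rate is worse; MMR is better",false
NONE,Matale,Rate and MMR are better,true
NONE,Matara,Rate and MMR are better,false
NONE,Moneragala,"Rate is worse; MMR is better",false
NONE,Nuwara Eliya,Rate and MMR are worse,false
NONE,Ratnapura,Rate and MMR are worse,false
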