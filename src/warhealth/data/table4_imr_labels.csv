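conflict_class,district,label
HIGH,Batticaloa,Rate and IMR are worse
HIGH,Jaffna,Rate and IMR are better
HIGH,Kilinochchi,Unable to determine
HIGH,Mannar,Rate and IMR are better
HIGH,Mullaitivu,Unable to determine
HIGH,Trincomalee,"Rate is worse; IMR is better"
HIGH,Vavuniya,Rate and IMR are worse
INTERMITTENT,Ampara,Rate and IMR are worse
INTERMITTENT,Anuradhapura,Rate and IMR are worse
INTERMITTENT,Polonnaruwa,Rate and IMR are worse
INTERMITTENT,Puttalam,Rate and IMR are better
NONE,Badulla,Rate and IMR are worse
NONE,Colombo,Unable to determine
NONE,Galle,"Rate is worse; IMR is better"
NONE,Gampaha,Unable to determine
NONE,Hambantota,"Rate is worse; IMR is better"
NONE,Kaluthara,Rate and IMR are worse
NONE,Kandy,Rate and IMR are worse
NONE,Kegalle,Rate and IMR are worse
NONE,Kurunegala,Rate and IMR are better
NONE,Matale,Rate and IMR are worse
NONE,Matara,Rate and IMR are better
NONE,Moneragala,"Rate is worse; IMR is better"
NONE,Nuwara Eliya,"Rate is worse; IMR is better"
NONE,Ratnapura,"Rate is worse; IMR is better"
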