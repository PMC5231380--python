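indicator,year,actual,cf_5yr,cf_10yr,trend_5yr,trend_10yr,trend_conflict,interpretation
IMR,1982,34.00,,,-0.04,-0.04,-0.02,"Improvements in IMR slowed during war. Absolute outcomes are worse than expected given pre-war trends."
IMR,2000,19.30,16.32,18.06,,,,
IMR,2002,18.20,15.04,16.83,,,,
MMR,1982,0.60,,,-0.08,-0.05,-0.04,"Improvement in maternal mortality slowed during the war. Outcome is inconclusive."
MMR,2002,0.14,0.11,0.20,,,,
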