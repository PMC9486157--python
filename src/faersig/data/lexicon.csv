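drug_key,name
ciprofloxacin,CIPROFLOXACIN
ciprofloxacin,CIPROFLOXACIN HYDROCHLORIDE
ciprofloxacin,CIPROFLOXACIN HCL
ciprofloxacin,CIPRO
ciprofloxacin,CIPRO XR
ciprofloxacin,CILOXAN
ciprofloxacin,CETRAXAL
ciprofloxacin,OTIPRIO
levofloxacin,LEVOFLOXACIN
levofloxacin,LEVOFLOXACIN HEMIHYDRATE
levofloxacin,LEVAQUIN
levofloxacin,QUIXIN
levofloxacin,IQUIX
moxifloxacin,MOXIFLOXACIN
moxifloxacin,MOXIFLOXACIN HYDROCHLORIDE
moxifloxacin,MOXIFLOXACIN HCL
moxifloxacin,AVELOX
moxifloxacin,MOXEZA
moxifloxacin,VIGAMOX
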