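event_key,pt_name,pt_code
tendonitis,Tendonitis,10043255
tendon_rupture,Tendon rupture,10043248
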