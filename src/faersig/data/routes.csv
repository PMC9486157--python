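route,route_class
oral,oral
intravenous,intravenous
intravenous (not otherwise specified),intravenous
intravenous drip,intravenous
intravenous bolus,intravenous
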