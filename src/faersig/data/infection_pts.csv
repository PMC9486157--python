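indi_pt
Urinary tract infection
Pneumonia
Bronchitis
Sinusitis
Cystitis
Pyelonephritis
Prostatitis
Diverticulitis
Gastroenteritis
Cellulitis
Sepsis
Tuberculosis
Bacteraemia
Osteomyelitis
Conjunctivitis
Otitis media
Otitis externa
Pharyngitis
Tonsillitis
Salmonellosis
Typhoid fever
Anthrax
Plague
Chronic obstructive pulmonary disease exacerbation
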