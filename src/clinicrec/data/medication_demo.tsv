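raw_name	ingredient
Norco	Acetaminophen-Hydrocodone
Vicodin	Acetaminophen-Hydrocodone
Lortab	Acetaminophen-Hydrocodone
Tylenol	Acetaminophen
Lopressor	Metoprolol
Toprol-XL	Metoprolol
Advil	Ibuprofen
Motrin	Ibuprofen
Coumadin	Warfarin
Lasix	Furosemide
Glucophage	Metformin
Zestril	Lisinopril
Prinivil	Lisinopril
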