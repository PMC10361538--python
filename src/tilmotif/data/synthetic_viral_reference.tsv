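cdr3	v.segm	antigen.epitope	antigen.species	reference_note
CASSIRSSYEQYF	TRBV19*01	SYN-GILG-M1	InfluenzaA-synthetic	fabricated synthetic entry
CASSPGQGDTQYF	TRBV9*01	SYN-NLVP-pp65	CMV-synthetic	fabricated synthetic entry
CASSLAPGTTNEKF	TRBV5-1*01	SYN-GLCT-BMLF1	EBV-synthetic	fabricated synthetic entry
CASSYVRTGELFF	TRBV6-5*01	SYN-YLQP-S1	SARSCoV2-synthetic	fabricated synthetic entry
CASSQDRVGNQYF	TRBV4-1*01	SYN-NLVP-pp65	CMV-synthetic	fabricated synthetic entry
CASSLGQAYNEQFF	TRBV7-9*01	SYN-RAKF-BZLF1	EBV-synthetic	fabricated synthetic entry
CASSIGTPYNEQFF	TRBV19*01	SYN-GILG-M1	InfluenzaA-synthetic	fabricated synthetic entry
CASSPDRGRYGYTF	TRBV27*01	SYN-TPRV-pp65	CMV-synthetic	fabricated synthetic entry
CASSFHGTDTQYF	TRBV12-3*01	SYN-YVLD-BRLF1	EBV-synthetic	fabricated synthetic entry
CASSLEGNTEAFF	TRBV28*01	SYN-YLQP-S1	SARSCoV2-synthetic	fabricated synthetic entry
CASSDRDRVNTEAF	TRBV9*01	SYN-IPSI-pp65	CMV-synthetic	fabricated synthetic entry
CASSQEGLAGVYTF	TRBV5-1*01	SYN-GLCT-BMLF1	EBV-synthetic	fabricated synthetic entry
CASSTTGGRETQYF	TRBV19*01	SYN-GILG-M1	InfluenzaA-synthetic	fabricated synthetic entry
CASSLVAGGSEQYF	TRBV6-5*01	SYN-NLVP-pp65	CMV-synthetic	fabricated synthetic entry
CASSRDWGSYEQYF	TRBV27*01	SYN-RAKF-BZLF1	EBV-synthetic	fabricated synthetic entry
CASSPKTGGNQPQH	TRBV28*01	SYN-YLQP-S1	SARSCoV2-synthetic	fabricated synthetic entry
CASSEARGLNTEAF	TRBV12-3*01	SYN-TPRV-pp65	CMV-synthetic	fabricated synthetic entry
CASSAGQGVSYEQY	TRBV7-9*01	SYN-GILG-M1	InfluenzaA-synthetic	fabricated synthetic entry
CASSLNRDSSYNEQ	TRBV5-1*01	SYN-IPSI-pp65	CMV-synthetic	fabricated synthetic entry
CASSYSDRGVETQY	TRBV9*01	SYN-YVLD-BRLF1	EBV-synthetic	fabricated synthetic entry
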