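superfamily	domain	peptide
Copia	INT	LQSDNGGEYTSNEFQEYCRSNGIQHQFTVPYTPQQNGVAERKNRT
Copia	RT	TAFLHGDLEEEIYMKQPEGFVDSKHPDYVCKLKKSLYGLKQSPRAWNKRF
Gypsy	RT	KTAFRTHEGHYEFLVMPFGLTNAPATFQALMNDVLRPYLGKFVVVYLDDILVYS
Gypsy	INT	FHVDFIGPLPKSNGYEYILVIVDYFSKWVEAFPTRTQEAVSVAKCLI
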