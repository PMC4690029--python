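# Toy TCA-like cycle: 8 compounds and 8 enzymes alternating, all activations.
# Relation form (reactions already converted); split at Oxaloacetate to linearize.
node	Oxaloacetate	compound
node	Citrate	compound
node	Isocitrate	compound
node	2-Oxoglutarate	compound
node	Succinyl-CoA	compound
node	Succinate	compound
node	Fumarate	compound
node	Malate	compound
node	CS	gene	CS
node	ACO2	gene	ACO2
node	IDH1	gene	IDH1
node	OGDH	gene	OGDH
node	SUCLA2	gene	SUCLA2
node	SDHA	gene	SDHA
node	FH	gene	FH
node	MDH2	gene	MDH2
edge	Oxaloacetate	CS	activation
edge	CS	Citrate	activation
edge	Citrate	ACO2	activation
edge	ACO2	Isocitrate	activation
edge	Isocitrate	IDH1	activation
edge	IDH1	2-Oxoglutarate	activation
edge	2-Oxoglutarate	OGDH	activation
edge	OGDH	Succinyl-CoA	activation
edge	Succinyl-CoA	SUCLA2	activation
edge	SUCLA2	Succinate	activation
edge	Succinate	SDHA	activation
edge	SDHA	Fumarate	activation
edge	Fumarate	FH	activation
edge	FH	Malate	activation
edge	Malate	MDH2	activation
edge	MDH2	Oxaloacetate	activation
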