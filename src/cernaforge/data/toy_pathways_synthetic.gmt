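sphingolipid_metabolism	SYNTHETIC demo set: membership invented for examples/tests, not a curated pathway	MAG	MYRF	PLP1	BCAS1	CARNS1	GJB1	MOG	SH3TC2
glutathione_metabolism	SYNTHETIC demo set: membership invented for examples/tests, not a curated pathway	HOXB3	MAG	MYRF	PLP1	LRAT	CYP2W1	MCOLN3	TUBAL3
control_set_unrelated	SYNTHETIC demo set: membership invented for examples/tests, not a curated pathway	ADAMTS14	ARGFX	CCBE1	CDCA3	MORC1	PRLR	SLC26A9	VSIG2
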