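sample_id	batch	class
A00	A	CTRL
A01	A	CTRL
A02	A	CTRL
A03	A	CTRL
A04	A	CTRL
A05	A	CTRL
A06	A	CTRL
A07	A	CTRL
A08	A	CTRL
A09	A	CTRL
B00	B	CTRL
B01	B	CTRL
B02	B	CTRL
B03	B	CTRL
B04	B	CTRL
B05	B	CTRL
B06	B	CTRL
B07	B	CTRL
B08	B	CTRL
B09	B	CTRL
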