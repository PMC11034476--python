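id	variant	reported	interpreted	combined_vep	consensus_model
V1	K4R	Benign	Benign	Benign	Benign
V2	G26R	Unknown	Pathogenic	Benign	Benign
V3	Q114H	Unknown	Pathogenic	Pathogenic	Benign
V4	R207W	Pathogenic	Pathogenic	Benign	Benign
V5	F315I	Pathogenic	Pathogenic	Pathogenic	Benign
V6	G322W	Unknown	Pathogenic	Pathogenic	Benign
V7	N331K	Pathogenic	Pathogenic	Pathogenic	Benign
V8	T394K	Pathogenic	Pathogenic	Benign	Pathogenic
V9	P397L	Pathogenic	Pathogenic	Pathogenic	Pathogenic
V10	A404P	Pathogenic	Pathogenic	Pathogenic	Pathogenic
V11	L411S	Unknown	Pathogenic	Pathogenic	Pathogenic
V12	L412M	Unknown	Pathogenic	Benign	Pathogenic
V13	S417R	Unknown	Pathogenic	Pathogenic	Pathogenic
V14	G424D	Pathogenic	Pathogenic	Pathogenic	Pathogenic
V15	I457N	Unknown	Pathogenic	Pathogenic	Pathogenic
V16	G466R	Pathogenic	Pathogenic	Pathogenic	Pathogenic
V17	D474G	Pathogenic	Pathogenic	Pathogenic	Pathogenic
V18	S477L	Pathogenic	Pathogenic	Pathogenic	Pathogenic
V19	L484F	Unknown	Pathogenic	Pathogenic	Benign
V20	A487S	Unknown	Benign	Benign	Benign
V21	C491Y	Pathogenic	Pathogenic	Pathogenic	Pathogenic
V22	R502C	Unknown	Benign	Pathogenic	Benign
V23	D506N	Benign	Benign	Benign	Benign
V24	M510K	Pathogenic	Pathogenic	Pathogenic	Pathogenic
V25	V539I	Pathogenic	Benign	Benign	Benign
V26	T550S	Unknown	Benign	Benign	Benign
V27	V552L	Unknown	Benign	Benign	Benign
V28	W556S	Unknown	Pathogenic	Pathogenic	Pathogenic
V29	M560V	Unknown	Benign	Benign	Benign
V30	G561R	Pathogenic	Pathogenic	Pathogenic	Benign
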