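nau_name	okamoto	lim	kim_d	other	sim_okamoto_lim	sim_lim_kimd
NAU-S1	S1	S6	S31		99.8%	100%
NAU-S2	S2	S2	S2		100%	100%
NAU-S3	S3	S12			99.9%
NAU-S4	S4	S7	S6		100%	100%
NAU-S5	S5
NAU-S6	S6	S18	S15		100%	100%
NAU-S7	S8
NAU-S8	S9	S21		S4/S5 (SP11-4/5)	99.3%	98.7%
NAU-S9	S11
NAU-S10	S14
NAU-S11	S15			S2 (SP11-2)	100%
NAU-S12	S17	S9	S5		99.7%	100%
NAU-S13	S18
NAU-S14	S19	S8	S7 (S30)		100%	100%
NAU-S15	S21
NAU-S16	S22 (S7)	S16	S13		100%	99.1%
NAU-S17	S23	S20	S16		99.9%	100%
NAU-S18	S25	S17			99.9%
NAU-S19	S26	S4		S1 (SP11-1)	100%	100%
NAU-S20	S28
NAU-S21	S29	S26		S3 (SP11-3)	99.4%	100%
NAU-S22	S30	S1	S1		100%	100%
NAU-S23	S31
NAU-S24		S5
NAU-S25		S10	S14			99.73%
NAU-S26		S11	S9 (S27)	S38 (DQ984139)		100%
NAU-S27		S15	S12			100%
NAU-S28		S22
NAU-S29		S23	S19			100%
NAU-S30		S24
NAU-S31		S27	S24			99.8%
NAU-S32		S29
NAU-S33		S30
NAU-S34		S31	S29			100%
NAU-S35			S4
NAU-S36			S8
NAU-S37			S10
NAU-S38			S11
NAU-S39			S17
NAU-S40			S18
NAU-S41			S20
NAU-S42			S21
NAU-S43			S22
NAU-S44			S23
NAU-S45			S25	S39		100%
NAU-S46			S28
NAU-S47				S201
NAU-S48				EF056499
NAU-S49				GQ121139
NAU-S50				S40
NAU-S51				S48
NAU-S52				S6
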