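probe_id	gene_symbol
202502_at	ACADM
221504_s_at	ATP6V1H
202654_x_at	AXOT
212460_at	C14orf147
203994_s_at	C21orf2
203996_s_at	C21orf2
208374_s_at	CAPZA1
217886_at	EPS15
218646_at	FLJ20534
204829_s_at	FOLR2
220131_at	FXYD7
217814_at	GK001
218092_s_at	HRB
212411_at	IMP4
200821_at	LAMP2
203276_at	LMNB1
214773_x_at	MGC3794
212803_at	NAB2
203371_s_at	NDUFB3
218047_at	OSBPL9
221123_x_at	PBF
208857_s_at	PCMT1
205202_at	PCMT1
209345_s_at	PI4KII
201222_s_at	RAD23B
201223_s_at	RAD23B
209207_s_at	SEC22L1
217758_s_at	SMBP
203605_at	SRP54
212513_s_at	USP33
201807_at	VPS26
210849_s_at	VPS41
205126_at	VRK2
216304_x_at	YME1L1
201351_s_at	YME1L1
222294_s_at	RAB27A
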