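sample_id	population	sex
CMT1	CMT	male
CMV1	CMV	unknown
CMM1	CMM	unknown
CMM2	CMM	unknown
CMM3	CMM	unknown
CMA1	CMA1	female
CMA2	CMA2	male
RMC1	RMC	unknown
RMC2	RMC	unknown
RMC3	RMC	unknown
RMI1	RMI	unknown
RMI2	RMI	unknown
JPM1	JPM	male
TWM1	TWM	male
TIM1	TIM	unknown
ASM1	ASM	unknown
STM1	STM	unknown
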