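# complete: false
# provenance: codes quoted in the running text of a published survey of 2051 bacterial NRPS A domains (partial transcription; the survey's full supplementary dataset is not bundled)
code	substrate	modifications	n	species	iterative	source
DAWFLGNVVK	Leu		1		false	Results/Leu-Ile-Val-Hpg
DAMFLGCTYK	Leu		1		false	Results/Leu-Ile-Val-Hpg
DALWIGGTFK	Leu		1		false	Results/Leu-Ile-Val-Hpg
DAWCIGAVCK	Leu		1		false	Results/Leu-Ile-Val-Hpg
DAWCIGAVCK	Phe		1		false	Results/Leu-Ile-Val-Hpg
DLYNLSGVWK	Ala		1		false	Results/Leu-Ile-Val-Hpg
DLYNLSGVWK	Leu		1		false	Results/Leu-Ile-Val-Hpg
DLYNLSGVWK	Val		1		false	Results/Leu-Ile-Val-Hpg
DAMHLGCTFK	Hpg		1		false	Results/Leu-Ile-Val-Hpg
DILHLGCTFK	Hpg		1		false	Results/Leu-Ile-Val-Hpg
DAWWIGGTFK	Dhv		1		false	Results/Leu-Ile-Val-Hpg
DAWFIGGTFK	Val		1		false	Results/Leu-Ile-Val-Hpg
DAWWLGGTFK	Val		1		false	Results/Leu-Ile-Val-Hpg
DVFWLGGTFK	Ala		1		false	Results/Ala-Abu-Met-Gly-Cys
DVFYLGGVFK	Met		1		false	Results/Ala-Abu-Met-Gly-Cys
DVFYLGGVCK	Met		1		false	Results/Ala-Abu-Met-Gly-Cys
DVWYLGGICK	Met		1		false	Results/Ala-Abu-Met-Gly-Cys
DILQLGMIWK	Gly	MOX	4		false	Results/Ala-Abu-Met-Gly-Cys
DLYNLSLIWK	Cys	Ox	1		false	Results/Ala-Abu-Met-Gly-Cys
DLYNMSLIWK	Cys	Ox	1		false	Results/Ala-Abu-Met-Gly-Cys
DLWNLSLIWK	Cys	Ox	1		false	Results/Ala-Abu-Met-Gly-Cys
DLYNLALVWK	Cys	Ox	1		false	Results/Ala-Abu-Met-Gly-Cys
DLYNWSLIWK	Cys	Ox	1		false	Results/Ala-Abu-Met-Gly-Cys
DGEACGGVTK	Orn		1		false	Results/Orn-Lys-Pro-Arg
DGECTGGITK	Orn		1		false	Results/Orn-Lys-Pro-Arg
DGEGSGGVTK	Orn		1		false	Results/Orn-Lys-Pro-Arg
DVWNIGLIHK	Orn		1		false	Results/Orn-Lys-Pro-Arg
DMEDVGSVDK	Orn		1		false	Results/Orn-Lys-Pro-Arg
DMEDVGSVDK	Lys		1		false	Results/Orn-Lys-Pro-Arg
DVETLGGISK	Orn		1		false	Results/Orn-Lys-Pro-Arg
DVETLGGISK	ANPA		1		false	Results/Orn-Lys-Pro-Arg
DGEDHGTVTK	Orn		1		false	Results/Orn-Lys-Pro-Arg
DGEDHGTVVK	Lys		1		false	Results/Orn-Lys-Pro-Arg
DVQCLSEVTK	AZC		1		false	Results/Orn-Lys-Pro-Arg
DMQLVSQQVK	AZC		1		false	Results/Orn-Lys-Pro-Arg
DIGDLGIIDK	Arg		1		false	Results/Orn-Lys-Pro-Arg (alpha,beta-dehydro-Arg)
DAEDVAAMIK	End		1		false	Results/Orn-Lys-Pro-Arg
DVESIGGVTK	Arg		1		false	Results/Orn-Lys-Pro-Arg
DVESIGGVTK	Har		1		false	Results/Orn-Lys-Pro-Arg
DAQDLGVVDK	Glu		1		false	Results/Glu-Gln-Asp-Asn
DAQDLGVVDK	Gln		1		false	Results/Glu-Gln-Asp-Asn
DLTKVGHVGK	Asp		1		false	Results/Glu-Gln-Asp-Asn
DLTKVGHVGK	Asn		1		false	Results/Glu-Gln-Asp-Asn
DAVQMGCVDK	Asn		1		false	Results/Glu-Gln-Asp-Asn
DAVQMGCVDK	Gln		1		false	Results/Glu-Gln-Asp-Asn
DLTKIGEVGK	Asn		1		false	Results/Glu-Gln-Asp-Asn
DLTKIGEVGK	Cya-3		1		false	Results/Glu-Gln-Asp-Asn
DPRHLALLAK	AMA		1		false	Results/Glu-Gln-Asp-Asn
DPRHVSLLAK	Asn		1		false	Results/Glu-Gln-Asp-Asn
DMFCAGLIWK	Thr		1		false	Results/Thr-Dhb
DMFSAGLIWK	Thr		1		false	Results/Thr-Dhb
DMFVAGLIWK	Thr		1		false	Results/Thr-Dhb
DFWNIGMVHK	Thr	N-Me;N,O-diMe	1		false	Results/Thr-Dhb
DFWSVGMVHK	Thr	gamma-Cl	1		false	Results/Thr-Dhb
DMFNFGVLWK	Thr	beta-OH	1		false	Results/Thr-Dhb
DMFCNGIIWK	Ser		1		false	Results/Thr-Dhb
DVWHLSLVDK	Ser		1		false	Results/Ser-Dha-Hse
DVWHLSLVDK	Dha		1		false	Results/Ser-Dha-Hse
DVWHMSLVDK	Ser		1		false	Results/Ser-Dha-Hse
DVWHMSLVDK	Dha		1		false	Results/Ser-Dha-Hse
DLKNVGSDVK	Hse/Hsl		1		false	Results/Ser-Dha-Hse
DLKNLGTDVK	Hse/Hsl		1		false	Results/Ser-Dha-Hse
DVSAIGCVTK	Tyr		1		false	Results/Tyr-Phe-Trp
DVSAIGCVTK	Phe		1		false	Results/Tyr-Phe-Trp
DVSAIGCVTK	Trp		1		false	Results/Tyr-Phe-Trp
DVWQMIGDDK	Dab	beta-OH	1		false	Results/Dab-Dap-His
DSALIAEVWK	His	beta-OH	1		false	Results/Dab-Dap-His
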