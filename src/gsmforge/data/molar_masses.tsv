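compound_id	name	molar_mass
C00062	arginine	174.20
C00047	lysine	146.19
C00123	leucine	131.17
C00407	isoleucine	131.17
C00073	methionine	149.21
C00135	histidine	155.15
C00079	phenylalanine	165.19
C00188	threonine	119.12
C00078	tryptophan	204.23
C00183	valine	117.15
C00305	magnesium	24.305
C00238	potassium	39.098
C00076	calcium	40.078
C00009	phosphate	94.97
C06428	EPA	302.45
C06429	DHA	328.49
C00031	D-glucose	180.16
C00267	alpha-D-glucose	180.16
C00095	fructose	180.16
C00089	sucrose	342.30
C00208	maltose	342.30
C00243	lactose	342.30
C00038	zinc	65.38
C00070	copper	63.546
C00023	iron	55.845
C00034	manganese	54.938
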