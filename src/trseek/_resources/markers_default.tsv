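set	gene
CD8	CD3D
CD8	CD3G
CD8	CD8A
CD8	CD8B
GZMK+Tem	GZMK
GZMK+Tem	CRTAM
Tex	HAVCR2
Tex	CTLA4
Tex	CXCL13
Temra	CX3CR1
Temra	GZMB
Trm	ZNF683
Trm	ITGAE
NK-like	KLRD1
NK-like	NKG7
Tn	CCR7
Tn	SELL
Tn	LEF1
Tm	IL7R
Tm	CD44
Proliferative	MKI67
Proliferative	TOP2A
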