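system	partner	kind	persistence
WT	L191	hydrophobic	81.7
WT	V265	hydrophobic	94.6
WT	L202	hydrophobic	27.1
WT	L203	hydrophobic	96.4
WT	V191-L202	hydrophobic	22.2
L213Q	V191-L202	hydrophobic	17.9
WT	V265-L203	hydrophobic	63.0
L213Q	V265-L203	hydrophobic	60.9
L213Q	N189	hbond	13.8
L213Q	C193	hbond	43.4
L213Q	Q199	hbond	53.9
L213Q	C206	hbond	19.9
L213Q	R263	hbond	18.0
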