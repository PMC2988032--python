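sample	tissue	variants
case11-normal	normal	T12519C,A14203G,T16126C,C16264T,A9221G,C13506T
case11-tumor	tumor	C6548T,T6827C,A6989G,A7055G,T7389C,C7915T,A8248G,C16270T,h12519,h12693,h14203,h16126,A7146G,C8468T,C8655T,T10810C,h11914,h11944,h13506,h13590,h13803,h15301
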