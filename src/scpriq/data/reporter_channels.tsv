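plex	label	formula
TMT11	126	C8 H16 N1
TMT11	127N	C8 H16 15N1
TMT11	127C	C7 13C1 H16 N1
TMT11	128N	C7 13C1 H16 15N1
TMT11	128C	C6 13C2 H16 N1
TMT11	129N	C6 13C2 H16 15N1
TMT11	129C	C5 13C3 H16 N1
TMT11	130N	C5 13C3 H16 15N1
TMT11	130C	C4 13C4 H16 N1
TMT11	131N	C4 13C4 H16 15N1
TMT11	131C	C3 13C5 H16 N1
TMTPro	126	C8 H16 N1
TMTPro	127N	C8 H16 15N1
TMTPro	127C	C7 13C1 H16 N1
TMTPro	128N	C7 13C1 H16 15N1
TMTPro	128C	C6 13C2 H16 N1
TMTPro	129N	C6 13C2 H16 15N1
TMTPro	129C	C5 13C3 H16 N1
TMTPro	130N	C5 13C3 H16 15N1
TMTPro	130C	C4 13C4 H16 N1
TMTPro	131N	C4 13C4 H16 15N1
TMTPro	131C	C3 13C5 H16 N1
TMTPro	132N	C3 13C5 H16 15N1
TMTPro	132C	C2 13C6 H16 N1
TMTPro	133N	C2 13C6 H16 15N1
TMTPro	133C	C1 13C7 H16 N1
TMTPro	134N	C1 13C7 H16 15N1
TMTPro	134C	13C8 H16 N1
TMTPro	135N	13C8 H16 15N1
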