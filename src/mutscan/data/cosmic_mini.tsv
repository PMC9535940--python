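protein_change	occurrence_count
S442I	2
L658Q	1
S768I	120
T790M	1200
L858R	3000
L927L	3
H1129Y	2
A289V	80
G719S	150
L861Q	200
G652R	1
E709K	25
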