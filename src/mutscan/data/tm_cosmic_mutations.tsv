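protein_change	occurrence_count
G652R	1
L658Q	1
A647T	2
I646V	3
L655F	2
G663C	1
G665V	1
M668I	2
I664T	1
P637S	2
R675Q	1
L679F	1
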