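>tm_region offset=631 transmembrane neighborhood, precursor numbering
PGLEGCPTNGPKIPSIATGMVGALLLLLVVALGIGLFMRRRHIVRKRTLRRLL
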