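allele	expressed_vehicle	expressed_ifng
HLA-A*11:01:01	False	False
HLA-A*24:02:01	True	True
HLA-B*35:08:01	True	True
HLA-B*55:01:01	True	True
HLA-C*01:02:01	True	True
HLA-C*04:01:01	True	True
HLA-DRA*01:01:01	True	True
HLA-DRA*01:02:02	True	True
HLA-DRB1*11:04:01	True	True
HLA-DRB1*13:03:01	True	True
HLA-DRB3*01:01:02	False	True
HLA-DRB3*02:02:01	False	True
HLA-DQA1*05:05:01	False	False
HLA-DQB1*03:01:01	True	True
HLA-DPA1*01:03:01	False	True
HLA-DPB1*04:01:01	False	True
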