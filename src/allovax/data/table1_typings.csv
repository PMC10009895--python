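subject_id,locus,allele
SV-BR-1-GM,HLA-A,11:01:01:01
SV-BR-1-GM,HLA-A,24:02:01:01
SV-BR-1-GM,HLA-B,35:08:01:01
SV-BR-1-GM,HLA-B,55:01:01
SV-BR-1-GM,HLA-C,01:02:01
SV-BR-1-GM,HLA-C,04:01:01:06
SV-BR-1-GM,HLA-DRA,01:01:01
SV-BR-1-GM,HLA-DRA,01:02:02
SV-BR-1-GM,HLA-DRB1,11:04:01
SV-BR-1-GM,HLA-DRB1,13:03:01
SV-BR-1-GM,HLA-DRB3,01:01:02:02
SV-BR-1-GM,HLA-DRB3,02:02:01:02
SV-BR-1-GM,HLA-DQA1,05:05:01
SV-BR-1-GM,HLA-DQB1,03:01:01:03
SV-BR-1-GM,HLA-DQB1,03:01:01
SV-BR-1-GM,HLA-DPA1,01:03:01
SV-BR-1-GM,HLA-DPB1,04:01:01
SV-BR-1-GM,HLA-DPB1,04:01:01
A001,HLA-A,02:01:01
A001,HLA-A,24:02:01:01
A001,HLA-B,13:02:01:01
A001,HLA-B,41:01:01
A001,HLA-C,06:02:01
A001,HLA-C,17:01:01:05
A001,HLA-DRB1,07:01:01
A001,HLA-DRB1,13:02:01:02
A001,HLA-DRB3,03:01:01
A001,HLA-DRB3,-
A001,HLA-DQB1,02:02:01
A001,HLA-DQB1,06:04:01
A001,HLA-DPB1,02:01:02
A001,HLA-DPB1,04:02:01
A002,HLA-A,02:01:01
A002,HLA-A,11:01:01:01
A002,HLA-B,18:03
A002,HLA-B,44:02:01:01
A002,HLA-C,05:01:01
A002,HLA-C,07:01:01
A002,HLA-DRB1,11:04:01
A002,HLA-DRB1,13:01:01
A002,HLA-DRB3,02:02:01:02
A002,HLA-DRB3,02:02:01:02
A002,HLA-DQB1,03:01:01:03
A002,HLA-DQB1,06:03:01
A002,HLA-DPB1,02:01:02
A002,HLA-DPB1,04:02:01
A003,HLA-A,02:01:01
A003,HLA-A,03:01:01:01
A003,HLA-B,07:02:01
A003,HLA-B,13:02:01:01
A003,HLA-C,06:02:01
A003,HLA-C,07:02:01
A003,HLA-DRB1,07:01:01
A003,HLA-DRB1,07:01:01
A003,HLA-DRB3,-
A003,HLA-DQB1,02:02:01
A003,HLA-DQB1,03:03:02:01
A003,HLA-DPB1,04:02:01
A003,HLA-DPB1,19:01:01
B001,HLA-A,11:01:01:01
B001,HLA-A,11:01:01:01
B001,HLA-B,35:01:01
B001,HLA-B,40:01:02
B001,HLA-C,03:04:01
B001,HLA-C,04:01:01:05
B001,HLA-DRB1,07:01:01
B001,HLA-DRB1,15:01:01
B001,HLA-DRB3,-
B001,HLA-DQB1,02:02:01
B001,HLA-DQB1,06:02:01:01
B001,HLA-DPB1,04:01:01
B001,HLA-DPB1,17:01:01:01
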