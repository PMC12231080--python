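fine_code,group
7000,aspen
7001,aspen
7002,cool_conifer
7003,cool_conifer
7004,cool_conifer
7005,warm_conifer
7006,warm_conifer
7007,warm_conifer
7008,warm_conifer
7009,mixed_aspen_conifer
7010,mixed_aspen_conifer
7011,herbaceous
7012,herbaceous
7013,shrub
7014,shrub
7015,woodland
7016,woodland
7017,wetland
7018,disturbed
7019,nonflammable
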