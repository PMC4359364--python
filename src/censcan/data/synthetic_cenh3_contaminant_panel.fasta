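>syn_fungal_cenh3_01
WKDMSTTFYIQLECSLGWVNDFIECWWIPYAVHKFKQCNTFDENPMQWVQRLWMVIGRIG
FKRKQPCARDDRSIWTTFITDNRKDYVRDSSTIVALQEEFTAYGYGLGLDTNQCAIHQKR
VIIMNKDFQLGGRARGGRA
>syn_fungal_cenh3_02
MFGLSMYYLTHNMYGFAWRHHKMKAPTMVTNQVSLTWYEENRISPDASTQSCNFLYHTWK
ELRKQPCKRGDRSIVTDFITDNRARWHGKSSTSVALQEESTAYEVGLGCDTNQCAIHQVR
VAIYNKDFQLGRRARLERA
>syn_fungal_cenh3_03
CPPWDAPYWSCHFSNVFPASRCFRWFHPISCTLIWRQPHQQHNEDLYDFCSLTFHPMMWG
CPRKQPCARLDRSIVTDFITDNRTIHKDSSSIVALQEEFTAYGRGLGLDTNQCAIHQKRV
MIMNKDFQLGRRARGEIA
>syn_fungal_cenh3_04
CLFNVRHWMKVNFAWCYCVIGDDCCALILGCVDGRYEVGIGLKSKLMDRENKVGHNYQPT
DARKQPCGRLDRSIPTDFITDPRIYTTKPDSSTIVILQEEFTAYGVGLGLDTNQCAIHQK
RVDIMNKAFQLVRRAHKERA
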