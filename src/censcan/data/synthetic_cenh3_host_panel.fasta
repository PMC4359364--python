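>syn_host_cenh3_01
DRDNVTYLHSSVAACWFPKAYPIEIWNDCVMDVPNTRYGFYPWMVKREYTMSGQNNDSPF
DGRKLPFKRLVEEIAQTFKTDLRKDEPSKAVMALQAYDECYLVGLWEDVNTCYYHAKRML
ISPLPIQLARRIRGEDA
>syn_host_cenh3_02
TPMEHESFTRAMQQFMLACETCPFLELCQQTKCMQRNLHAKIGHGEFRTMHLMYCDCYKQ
VMRKLPFVRAVEEIAQTFKCDLRAKMWQSKAVMALQAYDDVYLVFLWEDVNTCYIHAKRM
HISWLDSQLARRIRGEDA
>syn_host_cenh3_03
AFCKCHRMEGYWINKKLWHDHAQFKGYHTGNHLIERAYFDYMMKGAIANASWPEECVGWE
SCRKLPYDRLVEEIAQTFKTALRQVREQSKAVMALQAQDECYLVGLLEDVNTCYIMAKRM
AISPLPIQLAREIRGEDA
>syn_host_cenh3_04
FRGGKIAGQWFLPMVLQIWKCNCHNAFVYYRGISNAAWKGIQKQDTGSHFLSWQHILHTW
NFRKLPFTRLVMEIAQTLKTDLRELPFIQSGAVVALQAYDECYCVGLSEDVNTCYIHAKR
MDISPLDCQGARRIRYEDA
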