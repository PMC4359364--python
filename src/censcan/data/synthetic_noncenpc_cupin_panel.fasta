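>syn_noncenpc_cupin_01
HDEQEHDCKRSHPLRPHHEMGPLDQSENGKNLFHFEWGWYEDDIPEIAVSLMDQSIYTML
AEWMQWQTVWSHHEVWINKHCFQQTAVIFEPVHSSSTFDR
>syn_noncenpc_cupin_02
EDEQMHDCKFSHNIRPHTEFGPLDQSMNGKNLFTFEWVFYEDDIPEFAVSLYDQSIYTML
AEWMQWQTVWSHHEVWIQKPPFQQTALAFFPVHSSSTYDR
>syn_noncenpc_cupin_03
SDEQMHDCKFSHPIRPHHNFGGLDQSMNGKNLFAFRWGWYEDDIPEFAVSLCDQSIYTGL
AECMQWQTVWTHHEVWIDKPCFQQTALAFMPHHSSSTFDR
>syn_cupin_outgroup
HDRIMIDEVFLNSCMVSHSTGLECRMKNKGNKFWFDMIKFDDDFWTDKCSDIAKSMYQIH
AWNMKVQWFAHHHYWWLQLYCFTVTWGTKVCVHVQKCFKK
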