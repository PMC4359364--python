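>cenpc_motif_seed_01
IIVNSHFMAPALRDNYCNRVQEKW
>cenpc_motif_seed_02
IIVNEQFCNLALRNQYWNRVPETW
>cenpc_motif_seed_03
IIVNEQGCNPALRNKYWIRVPETW
>cenpc_motif_seed_04
YKKNYQHCNPCLRNNYWFVKPMTW
>cenpc_motif_seed_05
ISCNEQFCNPALRNNYWNRVGLTW
>cenpc_motif_seed_06
SIVNELVPNPALRMNYWNKVSETL
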