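>cenpc_cupin_seed_01
HDPWSHKCKDRYPIWFHAADGASGQGMNDAARFIFSWTRYFIDYITEKCYVRQKMCEVIT
AHWVPWLSGKHHHERCKDDPMETWTFWNIFGVHIISNHDH
>cenpc_cupin_seed_02
HDPWHHKCKKRYPMMFHHAEGPSCQGMNKFARNRFEWTRYFIDYITEKCYVRQKMIEVIT
HRWVQWLSGKWHHEDCQDKPMETWTFWNIFGFHIISAMDH
>cenpc_cupin_seed_03
NDPWSHKCKFRYPIMFHHAHGPSCQGMNKPPRFRFEWTRYFIDYITEKCTVVIKMIEVIT
AEWVQWLNGKHHKERCMDKAMETWTFFNNFGGHNISNHDH
>cenpc_cupin_seed_04
MDYWSHKCKFRYPIMFHHMDGPKCQGMNKAARFEFVHTRYFIDYIMEKCYVRQKMIEVIT
AEWVQALSRKHHHERCKDKPDETDTFWNIFYVHIISNHDH
>cenpc_cupin_seed_05
HDPWSHKCKFRYPIMFHHGDGPYCQGMNKAARFRHEWTRYLIDYITEKCYVRQKMIEVIT
AEWVQWVSTKHHHERCKDKPMETFTDWNIFGFHIISNVDH
>cenpc_cupin_seed_06
HDPQSHKCKFRYPIVFHHADGTSCQEMTKAARFRFNWTRYIIQVITEKCYVRQKMIEVIT
AEWVTWLSGKHHHERCKDKPMETWAFRNIFGVHIIHNHDH
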