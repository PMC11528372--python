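>synthetic_bR_like_template synthetic seven-helix opsin scaffold; canonical functional residues at BR positions (D85 T89 D96 E194 E204 D212 K216); numbering counted from residue 1
MQGKPPYDDLSFIIGSIAGIVAGWAFLMSSWGYAARSFVLIGVMLTTWAIITTGMVLLTT
LVGQKEYDYKERPKRYVWATFRAVDWMATFMGWLSDWIIIMKKQAAMGIVMLVAFWMMLI
FAAISWAIASGRYMVIGASGFVLIGLWSLFMMMFSVSQGEKQSSGMIIWSAISTVGGGFL
SYLMWIWWLIDKPEYQSDASIMSEAALMTWVDWMIKSLLGSFLLKSEDDKASYAGQYESD
RKTDTKDK
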