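# Default pharmacophore SMARTS patterns for USRCAT atom typing.
#
# These are functional, documented defaults; the set is configuration and may
# be replaced wholesale (CLI --smarts, or load_pattern_set).  Classes are
# independent: an atom may match several.
hydrophobic:
  - "[c,C;!$(C=[O,N,S]);!$(C#N)]"     # carbons without polar double/triple bonds
  - "[F,Cl,Br,I]"                     # halogens
  - "[S;D2;H0;$(S(C)C)]"              # thioether sulfur
aromatic:
  - "[a]"
donor:
  - "[#7;!H0]"                        # N-H bearers
  - "[#8;!H0]"                        # O-H bearers
  - "[#16;!H0]"                       # S-H bearers
acceptor:
  - "[O;!$([OX2H0][CX3]=[OX1])]"      # oxygens except ester/anhydride ether O
  - "[N;v3;!$([NX3][CX3]=[OX1]);!$([N+])]"  # basic trivalent nitrogens (not amide)
  - "[nX2]"                           # pyridine-type aromatic nitrogen
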