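# Default pharmacophore typing rules.
# One rule per line: SMARTS pattern, whitespace, label.
# The label is attached to the FIRST atom of each match; an atom's label set
# is the union over all matching rules, so rule order never matters.
# Unmatched atoms receive the Neutral label downstream.

# aromatic-perceived atoms
[a]                                                         Aromatic

# H-bond donors: N or O carrying at least one hydrogen
[#7,#8;!H0]                                                 Donor

# H-bond acceptors: N or O with a lone pair and formal charge <= 0
# (pyrrole-type aromatic NH donates its lone pair to the ring and is excluded)
[#7;!$([#7;+]);!$([nH])]                                    Acceptor
[#8;!$([#8;+])]                                             Acceptor

# hydrophobic atoms: uncharged C, S or halogen not bonded to a charged atom
[#6;+0;!$([#6]~[*;!+0])]                                    Hydrophobic
[#16;+0;!$([#16]~[*;!+0])]                                  Hydrophobic
[F,Cl,Br,I;+0;!$([*]~[*;!+0])]                              Hydrophobic

# positively ionizable: formal positive charge, or an aliphatic amine
[*;+,+2,+3]                                                 PosIonizable
[NX3;+0;!$([NX3][!#6]);!$([NX3][a]);!$([NX3][CX3]=[O,S,N])] PosIonizable

# negatively ionizable: formal negative charge, or an acid group OH
[*;-,-2,-3]                                                 NegIonizable
[OX2H1][CX3]=[OX1]                                          NegIonizable
[OX2H1][SX4](=[OX1])=[OX1]                                  NegIonizable
[OX2H1][PX4]=[OX1]                                          NegIonizable
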