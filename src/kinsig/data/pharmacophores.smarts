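# kinsig pharmacophore definitions
# version: 1
#
# Format: <class><TAB><SMARTS>, one pattern per line.  Multiple lines for the
# same class are OR-ed.  Every atom of every match receives the class label;
# all patterns here are written as single-atom queries with recursive
# environments so exactly one atom is labelled per match.
#
# Editing this file is a deliberate, versioned act: the test suite pins the
# labels these definitions produce on reference molecules.
Acceptor	[$([O;H1;v2;+0]),$([O;H0;v2;+0;!$(O=N)]),$([O;-;!$([O-][N+])]),$([N;v3;H0;+0;!$(N=*)]),$([N;v3;H1,H2;+0;!$(N[C,S,P]=[O,S,N]);!$(N=*);!$(N-a)]),$([n;+0;H0])]
Donor	[$([N;!H0;v3;+0]),$([N;!H0;+1;v4]),$([O;H1;+0]),$([S;H1;+0]),$([n;H1;+0])]
PosIonizable	[$([N;+1;!$(N=O);!$([N+][O-])]),$([NX3;H2;+0;$(N[CX4]);!$(NC=[O,N,S])]),$([NX3;H1;+0;$(N([CX4])[CX4]);!$(NC=[O,N,S])]),$([NX3;H0;+0;$(N([CX4])([CX4])[CX4])]),$([NX3;+0;$(NC(=[NX2;+0,+1])N)])]
NegIonizable	[$([OX2H1]C=O),$([OX1-]C=O),$([OX2H1]S(=O)=O),$([OX1-]S(=O)=O),$([OX2H1]P=O),$([OX1-]P=O)]
Aromatic	[a]
Hydrophobe	[C;H1,H2,H3;+0;!$(C~[#7,#8,#9,#15,#16,#17,#35,#53])]
Hydrophobe	[C;H0;+0;X4;!$(C~[#7,#8,#9,#15,#16,#17,#35,#53])]
Hydrophobe	[$([F;$(F[#6])]),$([Cl;$(Cl[#6])]),$([Br;$(Br[#6])]),$([I;$(I[#6])])]
Hydrophobe	[S;X2;H0;+0;$(S([#6])[#6])]
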