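// 39 functional-group SMARTS patterns (RDKit standard fragment catalog).
// First atom in each SMARTS is the attachment point, not part of the group.
-NC(=O)CH3	*-[N;D2]-[C;D3](=O)-[C;D1;H3]
-C(=O)O	*-C(=O)[O;D1]
-C(=O)OMe	*-C(=O)[O;D2]-[C;D1;H3]
-C(=O)H	*-C(=O)-[C;D1]
-C(=O)N	*-C(=O)-[N;D1]
-C(=O)CH3	*-C(=O)-[C;D1;H3]
-N=C=O	*-[N;D2]=[C;D2]=[O;D1]
-N=C=S	*-[N;D2]=[C;D2]=[S;D1]
-NO2	*-[N;D3](=[O;D1])[O;D1]
-N=O	*-[N;R0]=[O;D1]
=N-O	*=[N;R0]-[O;D1]
=NCH3	*=[N;R0]-[C;D1;H3]
-N=CH2	*-[N;R0]=[C;D1;H2]
-N=NCH3	*-[N;D2]=[N;D2]-[C;D1;H3]
-N=N	*-[N;D2]=[N;D1]
-N#N	*-[N;D2]#[N;D1]
-C#N	*-[C;D2]#[N;D1]
-SO2NH2	*-[S;D4](=[O;D1])(=[O;D1])-[N;D1]
-NHSO2CH3	*-[N;D2]-[S;D4](=[O;D1])(=[O;D1])-[C;D1;H3]
-SO3H	*-[S;D4](=O)(=O)-[O;D1]
-SO3CH3	*-[S;D4](=O)(=O)-[O;D2]-[C;D1;H3]
-SO2CH3	*-[S;D4](=O)(=O)-[C;D1;H3]
-SO2Cl	*-[S;D4](=O)(=O)-[Cl]
-SOCH3	*-[S;D3](=O)-[C;D1]
-SCH3	*-[S;D2]-[C;D1;H3]
-S	*-[S;D1]
=S	*=[S;D1]
-X	*-[#9,#17,#35,#53]
-tBu	*-[C;D4]([C;D1])([C;D1])-[C;D1]
-CF3	*-[C;D4](F)(F)F
-C#CH	*-[C;D2]#[C;D1;H]
-cPropyl	*-[C;D3]1-[C;D2]-[C;D2]1
-OEt	*-[O;D2]-[C;D2]-[C;D1;H3]
-OMe	*-[O;D2]-[C;D1;H3]
-O	*-[O;D1]
=O	*=[O;D1]
-N	*-[N;D1]
=N	*=[N;D1]
#N	*#[N;D1]
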