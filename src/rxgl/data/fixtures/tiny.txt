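CO.CCCCC(=O)O>>CCCCC(=O)OC.O	0
N#CC1CCC1>>CCCCC#N	1
CCCO.CCCC(=O)O>>CCCOC(=O)CCC	0
N#CC1CC1>>CCCC#N	1
CCO.CCCC(=O)O>>CCCC(=O)OCC	0
N#CC1CN1>>CNCC#N	1
CCCO.CC(=O)O>>CCCOC(C)=O.N	0
N#CC1CO1>>COCC#N.N.O	1
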