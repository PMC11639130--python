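CC(C)CO.CCCC(C)CCCCC(=O)O>>CCCCC(C)CCCC(=O)OCC(C)C	0
N#CC1CONCO1>>CONCOCC#N	1
CCCCCO.CCCCCCC(C)CC(=O)O>>CCCCCOC(=O)CCCCCCC(C)C.O	0
N#CC1CCCCN1>>CCCCNCC#N	1
CCC(C)CCCO.CCCCC(C)CCCCC(=O)O>>CCCCC(C)CCCCC(=O)OCCCC(C)CC	0
N#CC1CCCNN1>>CCCNNCC#N.N	1
CCCCCCCCCCCCO.CC(C)CCCCC(=O)O>>CCCCCCCCCCCCOC(=O)CC(C)CCCC	0
N#CC1CNONC1>>CNONCCC#N	1
CCCCCC(C)CO.CC(C)CCC(=O)O>>CCCCCC(C)COC(=O)CC(C)CC	0
N#CC1COCN1>>COCNCC#N	1
CCC(C)CCCCO.CCCCCCCCCCC(=O)O>>CCCCCCCCCCC(=O)OCCCCC(C)CC	0
N#CC1COCOC1>>COCOCCC#N	1
CCCCCCO.CCCCCCCC(C)CC(=O)O>>CCCCCCOC(=O)CCCCCCCC(C)C.S	0
N#CC1CNON1>>CNONCC#N	1
CCCCC(C)CCCCO.CCC(C)CCCCC(=O)O>>CCCCC(C)CCCCOC(=O)CCC(C)CCCC	0
N#CC1CCNCO1>>CCNCOCC#N	1
CCCCCCC(C)CCO.CCCCCCCCCCCCC(=O)O>>CCCCCCCCCCCCC(=O)OCCC(C)CCCCCC	0
N#CC1CNN1>>CNNCC#N	1
CO.CCCCCC(C)CC(=O)O>>COC(=O)CCCCCC(C)C	0
N#CC1COCNO1>>COCNOCC#N	1
CCCC(C)CCCO.CC(C)CCCCCC(=O)O>>CCCCCC(C)CC(=O)OCCCC(C)CCC	0
N#CC1CCCNO1>>CCCNOCC#N	1
CCCCCCCCO.CCCCC(=O)O>>CCCCCCCCOC(=O)CCCC	0
N#CC1CCNO1>>CCNOCC#N	1
CCC(C)CCCCO.CCCCCCCCC(=O)O>>CCCCCCCCC(=O)OCCCCC(C)CC	0
N#CC1COCON1>>COCONCC#N	1
CCCCCCC(C)CO.CC(C)CCC(=O)O>>CCCCCCC(C)COC(=O)CC(C)CC.P	0
N#CC1CNNOO1>>CNNOOCC#N	1
CCCCCCCO.CCCCCC(C)CC(=O)O>>CCCCCCCOC(=O)CCCCCC(C)C	0
N#CC1CNCNC1>>CNCNCCC#N	1
CCCCC(C)CO.CCCCCCCCC(=O)O>>CCCCCCCCC(=O)OCC(C)CCCC	0
N#CC1CCOOO1>>CCOOOCC#N	1
CCCO.CC(C)CCCCCCC(=O)O>>CCCCCCC(C)CC(=O)OCCC	0
N#CC1CCNON1>>CCNONCC#N	1
CCCCCCCCO.CCCC(C)CC(=O)O>>CCCCCCCCOC(=O)CCCC(C)C	0
N#CC1COOON1>>COOONCC#N	1
CCCCCCCC(C)CO.CCCCCCCCCCCCC(=O)O>>CCCCCCCCCCCCC(=O)OCC(C)CCCCCCC	0
N#CC1CNNO1>>CNNOCC#N	1
CCC(C)CCCCCO.CCCCCC(C)CC(=O)O>>CCC(C)CCCCCOC(=O)CCCCCC(C)C.F	0
N#CC1COCCO1>>COCCOCC#N	1
CCC(C)CCO.CCCCCCCCC(=O)O>>CCCCCCCCC(=O)OCCC(C)CC	0
N#CC1COON1>>COONCC#N	1
CCCCCCCCO.CC(C)CCCC(=O)O>>CCCCCCCCOC(=O)CC(C)CCC	0
N#CC1COCCN1>>COCCNCC#N	1
CCCCCCC(C)CCO.CC(C)CCCCCCC(=O)O>>CCCCCCC(C)CCOC(=O)CC(C)CCCCCC	0
N#CC1CCCOC1>>COCCCCC#N	1
CCCC(C)CCCCCO.CCC(C)CCC(=O)O>>CCCC(C)CCCCCOC(=O)CCC(C)CC.Cl	0
N#CC1CCNN1>>CCNNCC#N.Br	1
CC(C)CCCO.CCCCCCC(C)CCC(=O)O>>CCC(C)CCCCCCC(=O)OCCCC(C)C	0
N#CC1CNCOO1>>CNCOOCC#N	1
CCCCCCCCCCCCO.CC(=O)O>>CCCCCCCCCCCCOC(C)=O	0
N#CC1CNOOO1>>CNOOOCC#N	1
CCCCC(C)CCO.CCC(=O)O>>CCCCC(C)CCOC(=O)CC	0
N#CC1CCOOC1>>COOCCCC#N	1
CC(C)CCCCCO.CCCCCCC(C)CC(=O)O>>CC(C)CCCCCCC(=O)OCCCCCC(C)C.Cl	0
N#CC1CNCCN1>>CNCCNCC#N	1
CC(C)CCCCO.CCCCC(=O)O>>CCCCC(=O)OCCCCC(C)C	0
N#CC1CONN1>>CONNCC#N	1
CO.CCC(C)CC(=O)O>>COC(=O)CCC(C)C	0
N#CC1COONO1>>COONOCC#N	1
CCC(C)CO.CCCCCCCCCCCC(=O)O>>CCCCCCCCCCCC(=O)OCC(C)CC.I	0
N#CC1CNOC1>>CNOCCC#N	1
CCCCCCCCCO.CCCCC(C)CCCC(=O)O>>CCCCCCCCCOC(=O)CCCCC(C)CCC	0
N#CC1CCCN1>>CCCNCC#N	1
CCC(C)CCCO.CCCCCCCCCCCC(=O)O>>CCCCCCCCCCCC(=O)OCCCC(C)CC	0
N#CC1CCONC1>>CNOCCCC#N	1
CCCCCCCCCCCO.CC(C)CCCCCCC(=O)O>>CCCCCCCCCCCOC(=O)CC(C)CCCCCC	0
N#CC1CCNCN1>>CCNCNCC#N	1
CCCC(C)CCCO.CCCCC(=O)O>>CCCCC(=O)OCCCC(C)CCC	0
N#CC1CCO1>>CCOCC#N	1
CCC(C)CCCCO.CCCCCCCCCC(=O)O>>CCCCCCCCCC(=O)OCCCCC(C)CC	0
N#CC1CCON1>>CCONCC#N	1
CCC(C)CCCCCCO.CC(C)CCCCCC(=O)O>>CCCCCC(C)CC(=O)OCCCCCCC(C)CC	0
N#CC1CNNN1>>CNNNCC#N	1
CCCCCCCCO.CCCCCCC(=O)O>>CCCCCCCCOC(=O)CCCCCC.O	0
N#CC1CCCO1>>CCCOCC#N	1
CC(C)CCCCO.CCCC(C)CCC(=O)O>>CCC(C)CCCC(=O)OCCCCC(C)C	0
N#CC1CONOC1>>CONOCCC#N	1
CC(C)CCCCO.CCCCC(C)CCCCC(=O)O>>CCCCC(C)CCCCC(=O)OCCCCC(C)C	0
N#CC1CNCN1>>CNCNCC#N	1
CCCCCCC(C)CO.CCCCCCCCCCC(=O)O>>CCCCCCCCCCC(=O)OCC(C)CCCCCC	0
N#CC1CNNC1>>CNNCCC#N	1
CCCCC(C)CCCO.CCCCCCCCCCC(=O)O>>CCCCCCCCCCC(=O)OCCCC(C)CCCC	0
N#CC1CCN1>>CCNCC#N	1
CCCCCCC(C)CO.CCC(=O)O>>CCCCCCC(C)COC(=O)CC	0
N#CC1CCC1>>CCCCC#N	1
CCCCCCCCCO.CCCCC(=O)O>>CCCCCCCCCOC(=O)CCCC	0
N#CC1COCOO1>>COCOOCC#N	1
CCC(C)CCCCCCO.CCCC(C)CCC(=O)O>>CCC(C)CCCCCCOC(=O)CCCC(C)CC	0
N#CC1CNOO1>>CNOOCC#N.N.S	1
CCCCCC(C)CO.CCCCCCCCC(=O)O>>CCCCCCCCC(=O)OCC(C)CCCCC.P	0
N#CC1COOOC1>>COOOCCC#N.S	1
CCCC(C)CCCCO.CCCCC(C)CCCCC(=O)O>>CCCCC(C)CCCCC(=O)OCCCCC(C)CCC	0
N#CC1CNC1>>CNCCC#N	1
CCCCCCCCCCCCO.CC(C)CCCCCCC(=O)O>>CCCCCCCCCCCCOC(=O)CC(C)CCCCCC.F	0
N#CC1CCOON1>>CCOONCC#N	1
CCCCC(C)CO.CCC(C)CC(=O)O>>CCCCC(C)COC(=O)CCC(C)C	0
N#CC1CNCO1>>CNCOCC#N.Cl	1
CCC(C)CCCCCO.CC(=O)O>>CCC(C)CCCCCOC(C)=O	0
N#CC1CNNNC1>>CNNNCCC#N	1
CCCCCCCCCCCO.CCCCCCC(=O)O>>CCCCCCCCCCCOC(=O)CCCCCC.Br	0
N#CC1CCOCN1>>CCOCNCC#N.Br	1
CC(C)CCCCCCCO.CCC(=O)O>>CCC(=O)OCCCCCCCC(C)C.I	0
N#CC1CO1>>COCC#N	1
CCCC(C)CCCCCO.CC(C)CC(=O)O>>CCCC(C)CCCCCOC(=O)CC(C)C	0
N#CC1CCOC1>>COCCCC#N	1
CC(C)CCCCCO.CCCCC(C)CCCC(=O)O>>CCCC(C)CCCCC(=O)OCCCCCC(C)C	0
N#CC1COOO1>>COOOCC#N	1
CC(C)CCCCO.CCCC(C)CC(=O)O>>CC(C)CCCCOC(=O)CCCC(C)C	0
N#CC1CNNNO1>>CNNNOCC#N	1
CCCCCCCCCCO.CCC(=O)O>>CCCCCCCCCCOC(=O)CC	0
N#CC1CNCCO1>>CNCCOCC#N	1
CCCCCC(C)CCCO.CCCC(C)CCCCC(=O)O>>CCCCCC(C)CCCOC(=O)CCCC(C)CCCC	0
N#CC1CNOCN1>>CNOCNCC#N	1
CCC(C)CCCCO.CCCCCCCC(C)CC(=O)O>>CCC(C)CCCCOC(=O)CCCCCCCC(C)C	0
N#CC1CNNCN1>>CNNCNCC#N	1
CCC(C)CCCCCO.CCC(C)CC(=O)O>>CCC(C)CCCCCOC(=O)CCC(C)C	0
N#CC1CONOO1>>CONOOCC#N	1
CCC(C)CCCO.CC(=O)O>>CCC(C)CCCOC(C)=O	0
N#CC1CCNOC1>>CONCCCC#N	1
CC(C)CO.CCCCCC(=O)O>>CCCCCC(=O)OCC(C)C	0
N#CC1CNOON1>>CNOONCC#N.F.O	1
CCCCCCC(C)CO.CCCCCCC(=O)O>>CCCCCCC(=O)OCC(C)CCCCCC	0
N#CC1CONCN1>>CONCNCC#N	1
CCCO.CCC(C)CCC(=O)O>>CCCOC(=O)CCC(C)CC	0
N#CC1CNCON1>>CNCONCC#N	1
CC(C)CCCCCCCO.CCCC(C)CCCCCC(=O)O>>CCCCCC(C)CCCC(=O)OCCCCCCCC(C)C	0
N#CC1CNNON1>>CNNONCC#N	1
CCCCC(C)CCO.CCCCCCCCCC(=O)O>>CCCCCCCCCC(=O)OCCC(C)CCCC.P	0
N#CC1CCOCO1>>CCOCOCC#N	1
CCCCO.CCCCCC(=O)O>>CCCCCC(=O)OCCCC.O	0
N#CC1COCO1>>COCOCC#N.O	1
CCCCCCCCCO.CC(=O)O>>CCCCCCCCCOC(C)=O	0
N#CC1CCNCC1>>CCNCCCC#N	1
CCCCCC(C)CCO.CCCCCCCCCCCCC(=O)O>>CCCCCCCCCCCCC(=O)OCCC(C)CCCCC	0
N#CC1CNO1>>CNOCC#N.F	1
CCCCC(C)CCO.CCC(C)CCCCCCC(=O)O>>CCCCCCC(C)CCC(=O)OCCC(C)CCCC	0
N#CC1COOC1>>COOCCC#N	1
CCCCCCCCCO.CCCCCCCC(=O)O>>CCCCCCCCCOC(=O)CCCCCCC	0
N#CC1CCCON1>>CCCONCC#N	1
CC(C)CO.CCCCC(C)CCCCC(=O)O>>CCCCC(C)CCCCC(=O)OCC(C)C.N	0
N#CC1CC1>>CCCC#N	1
CCCC(C)CCCO.CCCCCCCCC(=O)O>>CCCCCCCCC(=O)OCCCC(C)CCC	0
N#CC1CCOCC1>>CCOCCCC#N.O	1
CCC(C)CCCCO.CCC(C)CCCCCCC(=O)O>>CCCCCCC(C)CCC(=O)OCCCCC(C)CC	0
N#CC1CCNNO1>>CCNNOCC#N	1
CC(C)CCCCCCO.CCCCCC(=O)O>>CCCCCC(=O)OCCCCCCC(C)C	0
N#CC1CONO1>>CONOCC#N	1
CCCCCCCC(C)CO.CCCCCC(=O)O>>CCCCCCCC(C)COC(=O)CCCCC	0
N#CC1CCCCC1>>CCCCCCC#N	1
CCCCC(C)CO.CC(C)CCCC(=O)O>>CCCCC(C)COC(=O)CC(C)CCC	0
N#CC1CCNC1>>CNCCCC#N	1
CCCC(C)CO.CC(C)CCCCCCCC(=O)O>>CCCCCCCC(C)CC(=O)OCC(C)CCC.Br.N	0
N#CC1CNNOC1>>CNNOCCC#N	1
CCCCCC(C)CCO.CCC(C)CCCCCC(=O)O>>CCCCCC(C)CCOC(=O)CCC(C)CCCCC	0
N#CC1CNONO1>>CNONOCC#N.P	1
CCCCCCC(C)CCO.CCC(C)CCCCCC(=O)O>>CCCCCCC(C)CCOC(=O)CCC(C)CCCCC	0
N#CC1CONON1>>CONONCC#N	1
CCC(C)CCO.CC(C)CCCCCCCC(=O)O>>CCCCCCCC(C)CC(=O)OCCC(C)CC	0
N#CC1CNOCO1>>CNOCOCC#N	1
CCCCCC(C)CCCO.CCCCCC(C)CC(=O)O>>CCCCCC(C)CCCOC(=O)CCCCCC(C)C	0
N#CC1CCONO1>>CCONOCC#N.I	1
CC(C)CCO.CCCCCCCCC(=O)O>>CCCCCCCCC(=O)OCCC(C)C.I	0
N#CC1CNNCO1>>CNNCOCC#N	1
CCCC(C)CCCO.CCCC(C)CCCC(=O)O>>CCCC(C)CCCOC(=O)CCCC(C)CCC.N	0
N#CC1CNOOC1>>CNOOCCC#N	1
CCCCCCC(C)CCO.CCCCC(C)CCCC(=O)O>>CCCCCCC(C)CCOC(=O)CCCCC(C)CCC.S	0
N#CC1CCCC1>>CCCCCC#N	1
CCCCCC(C)CCO.CCCCCC(C)CCCC(=O)O>>CCCCCC(C)CCOC(=O)CCCCCC(C)CCC	0
N#CC1COC1>>COCCC#N	1
CCCC(C)CCCCCO.CCCCC(C)CC(=O)O>>CCCC(C)CCCCCOC(=O)CCCCC(C)C	0
N#CC1CCNOO1>>CCNOOCC#N	1
CCCCC(C)CO.CCCC(C)CCCC(=O)O>>CCCCC(C)COC(=O)CCCC(C)CCC	0
N#CC1COOCO1>>COOCOCC#N.Cl	1
CCCCCO.CCCCCC(C)CCCC(=O)O>>CCCCCOC(=O)CCCCCC(C)CCC	0
N#CC1COO1>>COOCC#N	1
CCC(C)CCO.CCC(C)CCCCC(=O)O>>CCCCC(C)CCC(=O)OCCC(C)CC	0
N#CC1CCNNC1>>CNNCCCC#N	1
CCCCCCCCCCCCO.CC(C)CCCCCCCC(=O)O>>CCCCCCCCCCCCOC(=O)CC(C)CCCCCCC.N	0
N#CC1COOCN1>>COOCNCC#N	1
CC(C)CCCCO.CCC(C)CC(=O)O>>CC(C)CCCCOC(=O)CCC(C)C	0
N#CC1CCCNC1>>CNCCCCC#N	1
CCCCCC(C)CCO.CCCCCCCCCC(=O)O>>CCCCCCCCCC(=O)OCCC(C)CCCCC	0
N#CC1CNCOC1>>CNCOCCC#N	1
CCCCCCCCCCO.CCCCC(C)CCC(=O)O>>CCCCCCCCCCOC(=O)CCCCC(C)CC.P	0
N#CC1CCOO1>>CCOOCC#N	1
CCC(C)CCCCCCO.CCCCCC(C)CC(=O)O>>CCC(C)CCCCCCOC(=O)CCCCCC(C)C	0
N#CC1COOOO1>>COOOOCC#N	1
CCCCCCCO.CCCCCCCCC(=O)O>>CCCCCCCCC(=O)OCCCCCCC.S	0
N#CC1CONNO1>>CONNOCC#N.S	1
CCCC(C)CO.CCCCCC(C)CCC(=O)O>>CCCC(C)COC(=O)CCCCCC(C)CC	0
N#CC1CCCCO1>>CCCCOCC#N	1
CCCCCCCCCCCO.CCC(C)CC(=O)O>>CCCCCCCCCCCOC(=O)CCC(C)C	0
N#CC1CN1>>CNCC#N.P	1
CCCCCCC(C)CO.CCCCC(C)CCCC(=O)O>>CCCCCCC(C)COC(=O)CCCCC(C)CCC	0
N#CC1CCCOO1>>CCCOOCC#N	1
CC(C)CCO.CCC(=O)O>>CCC(=O)OCCC(C)C	0
N#CC1CNCNO1>>CNCNOCC#N	1
CCCCC(C)CCO.CCCC(C)CCC(=O)O>>CCCCC(C)CCOC(=O)CCCC(C)CC	0
N#CC1CON1>>CONCC#N	1
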