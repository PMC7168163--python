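name	mature_sequence	reported_length	reported_net_charge	reported_length_alt
Mcal mytilin 1	SCASRCKYRCRARRCRYYVSVRYGWFCYCRCLHC	34	9
Mcal mytilin 2	SCASRCKSRCRARRCKYYVSVRYGWFCYCRCLRC	34	10
Mcal mytilin 3	SCALLCKAHCRARRCGYYVSVFYHGRCYCRCLRC	34	7
Mcal mytilin 4	SCASKCKAVCRRRRCAGYDWVLWGGHCFCKCSRC	34	7
Mcal mytilin 5	SCASRCKYRCRRRRCRSYVAVRYCCRCLCKCRRC	34	13
Mcal mytilin 6	SCIPRCKYICTRRRRCGYYAAIYYCHRCYCKCLSC	35	8
Mcal PM	SCRTRCRFKCFGRGCGAYFAAQYGDFCYCKCYRC	34	6
Mcor mytilin 9	SCASRCKSRCRARRCRYYVAVRYGWFCYCRCLRC	34	10
Mgal mytilin L	YCPQSFRRICSSRCRGRGCQYYVAVCFPRRYYCKCLRC	38	9	39
Mgal mytilin M	SCASRCRSHCRARRCHYSKSVLVGRRCFCKCFLC	34	9
Mgal PM 2	SCRTRCRLKCFGRGCGAYFAAQRGPFCLCKCYRC	34	8
Mgal PM 3	SCRSRCRWKCFRRRCGAYFAAQRGPFCLCKCYRC	34	10
Pcan mytilin 1	SCDRWCNTSCYNKGCRYYAASVSDGRCFCCCITC	34	2
Pcan mytilin 2	NCARSCSSRCYHRNCKAYASVYRNETCYCCCIDC	34	3
Pcan mytilin 3	SCATSCSSRCEYRKCEDYASAIRDGKCYCCCIKC	34	2
Pcan mytilin 4	NCFSCPSTCARRGCRYFACATRLRKSYCCCFVC	33	6
Pcan mytilin 5	SCFSCPRTCGARGCRYYACATRFGTSYCCCFKC	33	5
Pcan mytilin 6	YCDLCRWYCSNKGCAYYLCGNKFGNNYCCCFKC	33	3
Pcan mytilin 7	YCDRCREYCSNTGCGYYMCVRRIVDRRLKYYCCCFKC	37	5
Pcan mytilin 8	GCGGCKYKCRRRGCRGYVCYKKRWLTICKCFRC	33	11
Pvir mytilin 1	SCATSCSSRCYNKGCKYYAAAIRSGTCYCCCFKG	34	5
Pvir mytilin 2	SCSSCPRTCGARGCRYYACATRLGTSYCCCFKC	33	5
Pvir mytilin 3	DCDSNCNHRCYYRGCKAYASALNNGTCYCCCVDC	43	0
Pvir mytilin 4	SCARCKDHCRNKGCGFYMCVLRYGTYYCCCFKC	33	5
Pvir mytilin 5	NCERCKYYCSYKNCSQYMCVRHNANDYCCCFNC	33	2
Pvir mytilin 6	ACDRCKAYCTIKGCGYYLCVHRFPSYYCCCFKC	33	4
Pvir mytilin 7	SCYTCKRRCAARGCRYYLCVIRYYRVYCGCYRC	33	8
Thir mytilin 1	SCSSICRYRCRRCRGFIWINIFGRCYCKCYGC	32	7
Thir mytilin 2	SCASSCKSRCRSRGCKYFVSVRYRYHCYCKCLRC	34	9
Thir mytilin 3	SCASRCKSRCRARRCKYYVSVRYGWFCYCKCLRC	34	10
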