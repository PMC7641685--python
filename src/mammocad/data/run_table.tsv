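arm	run	AC	SE	SP	AUOC
OS	1	75	68	78	81
DA	1	79	84	80	80
CS	1	92	87	95	91
DACS	1	93	94	97	91
OS	2	85	69	78	84
DA	2	69	66	73	82
CS	2	90	86	89	89
DACS	2	92	92	97	94
OS	3	75	81	75	75
DA	3	83	84	82	75
CS	3	91	88	90	94
DACS	3	89	89	97	93
OS	4	80	77	80	77
DA	4	77	80	86	84
CS	4	86	90	92	92
DACS	4	94	91	96	94
OS	5	69	68	81	79
DA	5	78	68	85	78
CS	5	89	86	89	88
DACS	5	92	92	98	95
OS	6	77	76	77	74
DA	6	75	75	83	77
CS	6	89	88	90	89
DACS	6	91	92	96	98
OS	7	80	75	83	73
DA	7	78	82	81	70
CS	7	87	89	93	93
DACS	7	94	92	95	98
OS	8	77	80	80	78
DA	8	76	73	79	88
CS	8	90	90	91	86
DACS	8	93	88	96	94
OS	9	81	72	76	81
DA	9	69	73	83	80
CS	9	89	90	91	92
DACS	9	94	91	98	97
OS	10	74	71	77	81
DA	10	72	76	83	82
CS	10	85	91	95	92
DACS	10	90	92	99	94
OS	11	80	72	74	76
DA	11	77	68	75	79
CS	11	89	88	93	87
DACS	11	93	92	96	95
OS	12	77	77	77	77
DA	12	83	86	77	76
CS	12	87	90	93	94
DACS	12	91	90	94	94
OS	13	77	70	78	77
DA	13	76	70	80	82
CS	13	89	88	92	86
DACS	13	94	93	97	95
OS	14	85	84	79	82
DA	14	72	74	82	74
CS	14	90	88	90	93
DACS	14	93	90	98	98
OS	15	77	75	84	73
DA	15	75	63	86	79
CS	15	85	86	91	88
DACS	15	89	93	98	94
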