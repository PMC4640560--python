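gene_id	sthubert_total	sthubert_5p	sthubert_3p	sthubert_fold	zonza_total	zonza_5p	zonza_3p	zonza_fold
Par-247	125	120	5	27.5	146	142	4	11.5
Par-341	52	51	1	10.5	70	69	1	5.0
Par-340	52	51	1	10.3	70	69	1	4.9
Pae-miR-989	288099	32	288067	5.2	873884	88	873796	5.6
Pae-miR-263a	24821	24819	2	4.5	63593	63591	2	4.1
B-0070/C-0072	291	173	118		574	130	444
B-0210/C-0160	97	9	88		262	19	243
B-0401/C-0173	27	6	21		137	8	129
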