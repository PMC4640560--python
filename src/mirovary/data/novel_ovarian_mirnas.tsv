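gene_id	precursor	mature_5p	mature_3p
B-0401/C-0173	agcugugcuauauuacaauccucaacauuuuccaaaguagugggcguaauuuaucgugagcuagcuauagauauuaugcucauuacuuuggauauguuguggaacuuacauc	uccaaaguagugggcguaauuuau	auauuaugcucauuacuuuggau
B-0042	guuuuuucuacacaagauguuugucagugacaguugucacucacucaguagacacguuuauauuguccugucacuggguguaguguuuacuaucacuguaacggacacuccau	guugucacucacucaguagaca	ucacuggguguaguguuuacuau
B-0070/C-0072	ugcugcaaugaaaagaagaacaaucuccauugguaguugucacucacucaguagacuagucauaaaccagucacugggugucugauuacuaucacuggugaucauuaccau	guugucacucacucaguagacu	ucacugggugucugauuacua
B-0112	acaaggucuuuaucguugacaguugucacucacucagaagacacguuaauauuguucugucacuggguguagugauuacuauc	guugucacucacucagaagaca	ucacuggguguagugauuacuau
B-0164	gcaguuuuacuuugaggguguuguuuaauuuuggccaguagaaguucuucaaaacuuauugcuucauuugguuucguuaguucaggauuuucauccccgguggacauagauaagu	uguuuaauuuuggccaguagaagu	ucauuugguuucguuaguucagga
B-0210/C-0160	caagaaguuugucagugacaguugucacucgcucaguagacacguuaauaauguucugucacuggguguagugauuacuaucaauguaauauauacuccaucacaaaaaaaa	guugucacucgcucaguagaca	ucacuggguguagugauuacu
B-0218	agugacaguugucacacacucaguagacacguuuauauuguccugucacuggguuuagugauuacuaucacuguaacggacacuccau	guugucacacacucaguagaca	ucacuggguuuagugauuacuau
B-0298	uaaaaguaggaauuaugagagagagaauuacggacauuggcgucauuauaaucagaugaccggaccagaucaguauacucgcucuggauacuacacacauccuaaucaacagg	gagagaauuacggacauuggcgu	cagaucaguauacucgcucugga
B-0319	uagggauaggaaauaacauuuucucuuuagcaaaaguuaucauucacucaguaggcuugucaucaaucagucacuggguauaugauuacuaucgcuaaugaucacaucgac	aaguuaucauucacucaguaggcu	ucacuggguauaugauuacua
C-0149	aaggucuuuaucguugacaguugucacucacucagaagacacguuaauauuguucugucacuggguguagugauuacuaucaaugcaauauacacuccauaacuacgaaca	guugucacucacucagaagaca	ucacuggguguagugauuacu
C-0261	ugucauuuggccccugaaauaauuggcacauguuauuuuuguagcugguuggcccauaugugcucaacuauggauuaugaagcaaagaaugcaagugucuuuuuaaaaugucaa	uauuuuuguagcugguuggcccau	uggauuaugaagcaaagaaugcaa
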