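atc_code	substance_name	class_label	group	ddd_value	ddd_unit	ddd_route
J01AA02	doxycycline	tetracycline	antibacterial	0.1	g
J01CE01	benzylpenicillin	penicillin_narrow	antibacterial	3.6	g	IV
J01CF02	cloxacillin	penicillin_blres	antibacterial	2	g
J01CR02	amoxicillin_clavulanate	penicillin_blinh	antibacterial	3	g	IV
J01CR05	piperacillin_tazobactam	penicillin_blinh	antibacterial	14	g	IV
J01DB04	cefazolin	cephalosporin_1st_gen	antibacterial	3	g	IV
J01DC02	cefuroxime	cephalosporin_2nd_gen	antibacterial	3	g	IV
J01DD01	cefotaxime	cephalosporin_3rd_gen	antibacterial	4	g	IV
J01DD02	ceftazidime	cephalosporin_3rd_gen	antibacterial	4	g	IV
J01DD04	ceftriaxone	cephalosporin_3rd_gen	antibacterial	2	g	IV
J01DH02	meropenem	carbapenem	antibacterial	3	g	IV
J01DH51	imipenem_cilastatin	carbapenem	antibacterial	2	g	IV
J01EE01	sulfamethoxazole_trimethoprim	sulfonamide_trimethoprim	antibacterial
J01FA09	clarithromycin	macrolide	antibacterial	0.5	g	PO
J01FA09	clarithromycin	macrolide	antibacterial	1	g	IV
J01FA10	azithromycin	macrolide	antibacterial	0.3	g	PO
J01FA10	azithromycin	macrolide	antibacterial	0.5	g	IV
J01FF01	clindamycin	lincosamide	antibacterial	1.2	g	PO
J01FF01	clindamycin	lincosamide	antibacterial	1.8	g	IV
J01GB01	tobramycin	aminoglycoside	antibacterial	0.24	g	IV
J01GB03	gentamicin	aminoglycoside	antibacterial	0.24	g	IV
J01GB06	amikacin	aminoglycoside	antibacterial	1	g	IV
J01MA02	ciprofloxacin	fluoroquinolone	antibacterial	1	g	PO
J01MA02	ciprofloxacin	fluoroquinolone	antibacterial	0.8	g	IV
J01MA12	levofloxacin	fluoroquinolone	antibacterial	0.5	g
J01XA01	vancomycin	glycopeptide	antibacterial	2	g
J01XA02	teicoplanin	glycopeptide	antibacterial	0.4	g	IV
J01XB01	colistin	polymyxin	antibacterial	3	g	IV
J01XD01	metronidazole	nitroimidazole	antibacterial	1.5	g	IV
J01XX08	linezolid	oxazolidinone	antibacterial	1.2	g
J01XX09	daptomycin	lipopeptide	antibacterial	0.28	g	IV
J04AB02	rifampicin	rifamycin	antibacterial	0.6	g
J02AA01	amphotericin_b	polyene	antifungal	35	mg	IV
J02AC01	fluconazole	triazole	antifungal	0.2	g
J02AC03	voriconazole	triazole	antifungal	0.4	g
J02AC04	posaconazole	triazole	antifungal	0.3	g
J02AX04	caspofungin	echinocandin	antifungal	50	mg	IV
J02AX05	micafungin	echinocandin	antifungal	0.1	g	IV
J02AX06	anidulafungin	echinocandin	antifungal	0.1	g	IV
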