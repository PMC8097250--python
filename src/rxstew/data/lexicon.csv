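# Package-supplied drug lexicon (synthetic stand-in for a proprietary roster); editable.
# keyword matches case-insensitively against the uppercased medication string;
# the longest matching keyword wins. One category per generic.
keyword,generic,category,class,subclass
PENICILLIN V,PENICILLIN V,antibiotic,penicillin,natural penicillin
AMOXICILLIN,AMOXICILLIN,antibiotic,penicillin,aminopenicillin
AMOXICILLIN-CLAVULANATE,AMOXICILLIN-CLAVULANATE,antibiotic,penicillin,beta-lactamase inhibitor combination
AMOX-CLAV,AMOXICILLIN-CLAVULANATE,antibiotic,penicillin,beta-lactamase inhibitor combination
AMPICILLIN,AMPICILLIN,antibiotic,penicillin,aminopenicillin
PIPERACILLIN-TAZOBACTAM,PIPERACILLIN-TAZOBACTAM,antibiotic,penicillin,beta-lactamase inhibitor combination
CEPHALEXIN,CEPHALEXIN,antibiotic,cephalosporin,first generation
CEFAZOLIN,CEFAZOLIN,antibiotic,cephalosporin,first generation
CEFUROXIME,CEFUROXIME,antibiotic,cephalosporin,second generation
CEFTRIAXONE,CEFTRIAXONE,antibiotic,cephalosporin,third generation
CEFDINIR,CEFDINIR,antibiotic,cephalosporin,third generation
CEFPODOXIME,CEFPODOXIME,antibiotic,cephalosporin,third generation
CEFEPIME,CEFEPIME,antibiotic,cephalosporin,fourth generation
MEROPENEM,MEROPENEM,antibiotic,carbapenem,carbapenem
ERTAPENEM,ERTAPENEM,antibiotic,carbapenem,carbapenem
IMIPENEM-CILASTATIN,IMIPENEM-CILASTATIN,antibiotic,carbapenem,carbapenem
AZTREONAM,AZTREONAM,antibiotic,monobactam,monobactam
CIPROFLOXACIN,CIPROFLOXACIN,antibiotic,fluoroquinolone,fluoroquinolone
LEVOFLOXACIN,LEVOFLOXACIN,antibiotic,fluoroquinolone,fluoroquinolone
MOXIFLOXACIN,MOXIFLOXACIN,antibiotic,fluoroquinolone,fluoroquinolone
AZITHROMYCIN,AZITHROMYCIN,antibiotic,macrolide,macrolide
CLARITHROMYCIN,CLARITHROMYCIN,antibiotic,macrolide,macrolide
FIDAXOMICIN,FIDAXOMICIN,antibiotic,macrolide,macrocyclic
DOXYCYCLINE,DOXYCYCLINE,antibiotic,tetracycline,tetracycline
MINOCYCLINE,MINOCYCLINE,antibiotic,tetracycline,tetracycline
TIGECYCLINE,TIGECYCLINE,antibiotic,tetracycline,glycylcycline
SULFAMETHOXAZOLE-TRIMETHOPRIM,SULFAMETHOXAZOLE-TRIMETHOPRIM,antibiotic,sulfonamide,folate pathway inhibitor
SMZ-TMP,SULFAMETHOXAZOLE-TRIMETHOPRIM,antibiotic,sulfonamide,folate pathway inhibitor
NITROFURANTOIN,NITROFURANTOIN,antibiotic,nitrofuran,nitrofuran
METRONIDAZOLE,METRONIDAZOLE,antibiotic,nitroimidazole,nitroimidazole
CLINDAMYCIN,CLINDAMYCIN,antibiotic,lincosamide,lincosamide
VANCOMYCIN,VANCOMYCIN,antibiotic,glycopeptide,glycopeptide
LINEZOLID,LINEZOLID,antibiotic,oxazolidinone,oxazolidinone
DAPTOMYCIN,DAPTOMYCIN,antibiotic,lipopeptide,lipopeptide
GENTAMICIN,GENTAMICIN,antibiotic,aminoglycoside,aminoglycoside
TOBRAMYCIN,TOBRAMYCIN,antibiotic,aminoglycoside,aminoglycoside
AMIKACIN,AMIKACIN,antibiotic,aminoglycoside,aminoglycoside
LISINOPRIL,LISINOPRIL,antihypertensive,antihypertensive,ACE-I
ENALAPRIL,ENALAPRIL,antihypertensive,antihypertensive,ACE-I
RAMIPRIL,RAMIPRIL,antihypertensive,antihypertensive,ACE-I
LOSARTAN,LOSARTAN,antihypertensive,antihypertensive,ARB
VALSARTAN,VALSARTAN,antihypertensive,antihypertensive,ARB
OLMESARTAN,OLMESARTAN,antihypertensive,antihypertensive,ARB
METOPROLOL,METOPROLOL,antihypertensive,antihypertensive,beta-blocker
ATENOLOL,ATENOLOL,antihypertensive,antihypertensive,beta-blocker
CARVEDILOL,CARVEDILOL,antihypertensive,antihypertensive,beta-blocker
PROPRANOLOL,PROPRANOLOL,antihypertensive,antihypertensive,beta-blocker
METFORMIN,METFORMIN,other,,
ATORVASTATIN,ATORVASTATIN,other,,
LEVOTHYROXINE,LEVOTHYROXINE,other,,
OMEPRAZOLE,OMEPRAZOLE,other,,
FUROSEMIDE,FUROSEMIDE,other,,
SERTRALINE,SERTRALINE,other,,
DONEPEZIL,DONEPEZIL,other,,
APIXABAN,APIXABAN,other,,
WARFARIN,WARFARIN,other,,
AMLODIPINE,AMLODIPINE,other,,
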