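# Package-supplied antibiotic spectrum index scores (synthetic stand-in on the
# published 1-13 scale: 1 = narrowest, 13 = broadest spectrum); editable.
generic,asi
PENICILLIN V,2
AMOXICILLIN,4
AMOXICILLIN-CLAVULANATE,7
AMPICILLIN,4
PIPERACILLIN-TAZOBACTAM,10
CEPHALEXIN,3
CEFAZOLIN,3
CEFUROXIME,5
CEFTRIAXONE,6
CEFDINIR,5
CEFPODOXIME,5
CEFEPIME,8
MEROPENEM,11
ERTAPENEM,9
IMIPENEM-CILASTATIN,11
AZTREONAM,5
CIPROFLOXACIN,7
LEVOFLOXACIN,8
MOXIFLOXACIN,9
AZITHROMYCIN,4
CLARITHROMYCIN,4
FIDAXOMICIN,1
DOXYCYCLINE,7
MINOCYCLINE,7
TIGECYCLINE,13
SULFAMETHOXAZOLE-TRIMETHOPRIM,5
NITROFURANTOIN,2
METRONIDAZOLE,2
CLINDAMYCIN,4
VANCOMYCIN,4
LINEZOLID,4
DAPTOMYCIN,4
GENTAMICIN,6
TOBRAMYCIN,6
AMIKACIN,7
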