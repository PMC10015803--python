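chemical,cas,rv,rv_source,oel_se,oel_se_source,oel_nordic,oel_nordic_source,oel_intl,oel_intl_source,note
1-Methoxy-2-propanol,107-98-2,7000,published RV compilation,,,,,,,
2-Buthoxyethanol,111-76-2,1600,published RV compilation,,,,,,,
2-Butoxyethylacetate,112-07-2,150,published RV compilation,,,,,,,
2-Ethylhexanol,104-76-7,540,published RV compilation,,,,,,,
2-Phenoxyethanol,122-99-6,,,,,,,5700,IFA (Germany),
"2,4-Toluene diisocyanate",584-84-9,,,14,IFA (Sweden),,,,,
"2,6-Toluene diisocyanate",91-08-7,,,14,IFA (Sweden),,,,,
Acetaldehyde,75-07-0,140,published RV compilation,,,,,,,
Acetone,67-64-1,70000,published RV compilation,,,,,,,
a-pinene,80-56-8,450,published RV compilation,,,,,,,
Decanal,112-31-2,,,,,,,,,no RV or OEL found
Decane,124-18-5,6000,published RV compilation,,,,,,,
Dihydromyrcenol,18479-58-8,,,,,,,,,no RV or OEL found
Dodecanol,112-53-8,,,,,,,1000,IFA (Latvia),
Formaldehyde,59-00-0,9,published RV compilation,,,,,,,CAS kept as printed in the source table; the standard formaldehyde CAS is 50-00-0
Hedione,24851-98-7; 2630-39-9,,,,,,,,,no RV or OEL found
Hexadecanol,36653-82-4,,,,,,,,,no RV or OEL found
Isopropanol,67-63-0,7,published RV compilation,,,,,,,
Limonene,5989-27-5,450,published RV compilation,,,,,,,
MEK; 2-Butanone,78-93-3,5000,published RV compilation,,,,,,,
Nonane,111-84-2,200,published RV compilation,,,,,,,
Nonanal,124-19-6,,,,,,,,,no RV or OEL found
Octanal,124-13-0,650,published RV compilation,,,,,,,
Propylene glycol,57-55-6,,,,,,,,,no RV or OEL found
Siloxanes; silicones,14857-34-2,,,,,2100,IFA (Denmark) — footnoted Dimethylethoxysiloxane,,,OEL stored as printed for the grouped analyte without resolving the chemistry
Toluene,108-88-3,260,WHO,,,,,,,
Undecane,1120-21-4,6000,published RV compilation,,,,,,,
Vertenex compound,NA,,,,,,,,,no specific structure available; no RV or OEL found
Xylene,95-47-6; 108-38-3; 106-42-3,200,ATSDR,,,,,,,
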