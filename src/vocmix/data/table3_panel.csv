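chemical,cas,chem_class,tvoc_included,gm,gsd,detect_prob
1-Methoxy-2-propanol,107-98-2,VOC,true,12,1.8,0.066667
2-Buthoxyethanol,111-76-2,VOC,true,6.2,1.6,0.1
2-Butoxyethylacetate,112-07-2,VOC,true,7,1.0,0.033333
2-Ethylhexanol,104-76-7,VOC,true,6.9,4.4,0.3
2-Phenoxyethanol,122-99-6,VOC,true,9.1,1.8,0.7
"2,4-Toluene diisocyanate",584-84-9,VOC,true,10,1.0,0.033333
"2,6-Toluene diisocyanate",91-08-7,VOC,true,12,1.0,0.033333
Acetaldehyde,75-07-0,aldehyde,true,11,2.0,0.533333
Acetone,67-64-1,VOC,true,42,2.0,0.966667
a-pinene,80-56-8,VOC,true,8.6,2.5,0.133333
Decanal,112-31-2,aldehyde,true,8.7,1.6,0.433333
Decane,124-18-5,VOC,true,7.1,1.6,0.066667
Dihydromyrcenol,18479-58-8,VOC,true,6.8,2.0,0.4
Dodecanol,112-53-8,VOC,true,8.7,2.6,0.733333
Formaldehyde,59-00-0,aldehyde,true,11,1.9,0.666667
Hedione,24851-98-7; 2630-39-9,VOC,true,6.9,2.4,0.333333
Hexadecanol,36653-82-4,VOC,true,12,3.7,0.566667
Isopropanol,67-63-0,VOC,true,58,1.0,0.033333
Limonene,5989-27-5,VOC,true,18,4.1,0.733333
MEK; 2-Butanone,78-93-3,VOC,true,6,1.0,0.066667
Nonane,111-84-2,VOC,true,2.0,1.5,0.033333
Nonanal,124-19-6,aldehyde,true,9.4,1.7,0.6
Octanal,124-13-0,aldehyde,true,13,1.5,0.166667
Propylene glycol,57-55-6,VOC,true,13,2.1,0.866667
Siloxanes; silicones,14857-34-2,VOC,true,100,4.3,0.966667
Toluene,108-88-3,VOC,true,21,1.3,0.2
Undecane,1120-21-4,VOC,true,7.8,1.4,0.066667
Vertenex compound,NA,VOC,true,8.0,2.0,0.7
Xylene,95-47-6; 108-38-3; 106-42-3,VOC,true,2.0,1.5,0.033333
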