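measurand,cvi,cvg
APTT,2.8,7.2
ALT,11.4,35.2
AST,2.5,4.1
ALP,6.0,21.0
"Bilirubin, total",20.2,24.6
Chloride,1.0,1.3
"Cholesterol, total",5.2,15.3
Creatinine,4.4,16.2
RBC,2.8,7.0
Glucose,4.6,8.1
Hematocrit,2.8,5.6
Hemoglobin,2.7,6.2
MCV,0.8,3.9
Potassium,3.9,5.3
PSA,6.8,42.0
"Protein, total",2.6,3.5
PT,2.6,5.1
Sodium,0.5,0.7
TSH,17.9,36.1
Urea,13.3,20.6
WBC,11.1,17.2
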