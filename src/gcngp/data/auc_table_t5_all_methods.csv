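disease,GCNGP,C-PUGP,DADA,HSSVM,GPEC,Arete,WCR_STAR_,TLGP,GPrior
Pancreatitis,80.76,76.95,71.99,68.51,50.72,67.55,72.26,77.12,74.71
Parkinson's disease,75.28,69.72,61.45,57.38,48.65,51.39,68.48,71.86,68.95
Celiac disease,77.95,71.07,67.61,61.27,42.96,53.02,72.28,73.90,70.43
Atherosclerosis,80.25,78.81,73.66,70.33,61.48,64.14,75.80,78.09,75.24
Esophageal cancer,78.61,76.15,69.63,65.95,60.52,63.38,69.92,74.55,69.78
Crohn's disease,69.90,66.39,62.05,59.89,52.66,60.16,66.21,66.98,64.36
Breast cancer,74.08,71.22,68.76,68.29,55.79,61.05,69.54,72.57,69.19
Alzheimer's disease,76.39,69.76,66.18,61.90,59.37,67.80,68.17,71.83,68.42
Ulcerative colitis,67.83,61.98,59.03,57.64,49.13,59.74,62.97,63.81,62.85
Endometriosis,84.30,80.59,74.84,70.61,53.85,77.32,79.53,80.87,79.66
Cirrhosis,59.92,55.09,51.76,49.47,41.62,52.97,56.88,55.69,54.18
Myocardial infarction,71.48,65.83,60.91,56.17,44.21,55.82,66.02,67.71,64.13
Tuberculosis,78.75,74.07,67.22,66.19,52.98,67.46,71.44,75.05,73.22
Lymphoma,73.87,71.65,58.11,55.72,50.78,54.29,72.68,71.93,71.07
Rheumatoid arthritis,66.09,62.53,61.68,59.16,55.73,55.89,61.95,62.64,61.16
Asthma,63.94,59.86,54.82,55.27,53.04,57.98,58.85,60.28,58.39
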