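disease,GCNGP,GCAS,RGCN,PGCN,GCN-MF
Pancreatitis,80.76,73.38,76.18,78.01,78.57
Parkinson's disease,75.28,71.25,70.90,74.59,73.16
Celiac disease,77.95,73.81,70.39,71.27,75.82
Atherosclerosis,80.25,76.66,73.11,75.05,75.98
Esophageal cancer,78.61,75.15,74.77,75.86,79.10
Crohn's disease,69.90,65.49,63.26,65.07,67.44
Breast cancer,74.08,71.69,71.87,70.78,72.88
Alzheimer's disease,76.39,73.94,70.85,69.97,74.29
Ulcerative colitis,67.83,65.81,62.19,62.92,64.66
Endometriosis,84.30,81.17,79.67,79.95,83.13
Cirrhosis,59.92,56.94,55.09,56.19,57.75
Myocardial infarction,71.48,70.18,67.75,66.54,69.49
Tuberculosis,78.75,75.97,71.54,70.72,76.91
Lymphoma,73.87,72.45,69.19,70.04,71.97
Rheumatoid arthritis,66.09,64.93,63.17,61.59,64.68
Asthma,63.94,60.74,59.13,59.91,61.39
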