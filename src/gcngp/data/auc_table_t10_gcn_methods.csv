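disease,GCNGP,GCAS,RGCN,PGCN,GCN-MF
Pancreatitis,93.65,90.44,88.18,89.05,89.25
Parkinson's disease,88.82,87.29,84.75,83.69,85.90
Celiac disease,87.39,83.08,82.77,80.88,85.10
Atherosclerosis,96.55,92.97,89.35,91.64,94.89
Esophageal cancer,87.44,85.15,84.58,81.29,86.96
Crohn's disease,82.73,81.36,78.84,80.01,80.52
Breast cancer,87.66,84.49,81.69,83.13,85.73
Alzheimer's disease,90.45,85.25,83.86,82.49,88.27
Ulcerative colitis,79.36,75.77,72.61,74.16,77.07
Endometriosis,96.05,95.29,91.54,89.99,92.43
Cirrhosis,74.48,71.01,69.37,70.71,72.55
Myocardial infarction,91.69,86.82,82.95,85.36,89.18
Tuberculosis,95.35,94.66,91.62,92.13,93.69
Lymphoma,92.81,88.91,86.25,85.79,90.14
Rheumatoid arthritis,84.97,83.54,80.08,81.22,82.25
Asthma,86.19,83.09,82.92,83.88,84.24
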