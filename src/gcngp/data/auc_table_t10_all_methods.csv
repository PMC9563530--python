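disease,GCNGP,C-PUGP,DADA,HSSVM,GPEC,Arete,WCR_STAR_,TLGP,GPrior
Pancreatitis,93.65,87.58,85.19,79.24,66.86,72.39,81.10,90.01,86.25
Parkinson's disease,88.82,76.84,69.98,68.84,60.92,66.48,77.66,83.65,75.19
Celiac disease,87.39,79.75,74.25,70.15,59.28,69.36,80.85,79.17,71.92
Atherosclerosis,96.55,91.66,90.08,81.95,72.67,79.14,89.28,92.40,90.38
Esophageal cancer,87.44,86.78,81.63,78.11,71.09,76.38,78.34,85.82,82.59
Crohn's disease,82.73,80.25,77.29,76.85,69.16,76.50,79.09,80.07,78.44
Breast cancer,87.66,85.62,80.76,75.70,70.05,73.81,81.54,86.38,82.11
Alzheimer's disease,90.45,82.19,83.64,82.96,76.27,80.25,84.17,85.87,81.95
Ulcerative colitis,79.36,78.46,77.96,71.27,69.91,72.74,75.52,77.98,75.16
Endometriosis,96.05,90.44,88.32,85.50,70.85,81.65,87.76,91.16,89.18
Cirrhosis,74.48,70.91,71.80,66.67,59.09,68.04,71.45,71.43,70.62
Myocardial infarction,91.69,87.35,87.95,82.41,68.66,75.90,85.69,89.05,86.57
Tuberculosis,95.35,91.80,89.15,80.29,71.18,79.82,90.13,92.34,90.48
Lymphoma,92.81,88.39,85.78,82.33,73.06,82.66,89.92,89.15,86.39
Rheumatoid arthritis,84.97,80.16,80.72,72.54,70.33,71.68,79.35,80.93,78.69
Asthma,86.19,83.92,81.18,79.46,64.47,77.49,80.97,83.11,81.27
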