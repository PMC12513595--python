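pt	soc
Disseminated enteroviral infection	Infections and infestations
Meningitis enteroviral	Infections and infestations
Post-acute COVID-19 syndrome	Infections and infestations
Sinusitis aspergillus	Infections and infestations
Cytomegalovirus enterocolitis	Infections and infestations
Coronavirus pneumonia	Infections and infestations
Cytomegalovirus chorioretinitis	Infections and infestations
Cytomegalovirus gastroenteritis	Infections and infestations
Cytomegalovirus hepatitis	Infections and infestations
COVID-19 pneumonia	Infections and infestations
Pneumonia haemophilus	Infections and infestations
Superinfection bacterial	Infections and infestations
Campylobacter gastroenteritis	Infections and infestations
Campylobacter infection	Infections and infestations
Neutropenic infection	Infections and infestations
Sinobronchitis	Infections and infestations
Listeria sepsis	Infections and infestations
COVID-19	Infections and infestations
Pneumonia cytomegaloviral	Infections and infestations
Progressive multifocal leukoencephalopathy	Infections and infestations
Enterobacter bacteraemia	Infections and infestations
Cytomegalovirus infection	Infections and infestations
Coronavirus infection	Infections and infestations
Hepatitis B	Infections and infestations
Cytomegalovirus viraemia	Infections and infestations
Hepatitis B reactivation	Infections and infestations
Sinusitis	Infections and infestations
Cytomegalovirus infection reactivation	Infections and infestations
Aspergillus infection	Infections and infestations
Pneumonia	Infections and infestations
Sepsis	Infections and infestations
Urinary tract infection	Infections and infestations
Gastroenteritis	Infections and infestations
Bone marrow necrosis	Blood and lymphatic system disorders
Myelosuppression	Blood and lymphatic system disorders
Cytopenia	Blood and lymphatic system disorders
Aplasia pure red cell	Blood and lymphatic system disorders
Lymphopenia	Blood and lymphatic system disorders
Haematotoxicity	Blood and lymphatic system disorders
Aplastic anaemia	Blood and lymphatic system disorders
Neutropenia	Blood and lymphatic system disorders
Thrombocytopenia	Blood and lymphatic system disorders
Anaemia	Blood and lymphatic system disorders
Leukopenia	Blood and lymphatic system disorders
Febrile neutropenia	Blood and lymphatic system disorders
Cytomegalovirus test positive	Investigations
Human rhinovirus test positive	Investigations
Procalcitonin increased	Investigations
CD4 lymphocytes decreased	Investigations
Alanine aminotransferase increased	Investigations
Aspartate aminotransferase increased	Investigations
Blood creatinine increased	Investigations
Neutrophil count decreased	Investigations
Platelet count decreased	Investigations
White blood cell count decreased	Investigations
Lymphocyte count decreased	Investigations
Weight decreased	Investigations
Tumour lysis syndrome	Metabolism and nutrition disorders
Hyperphosphataemia	Metabolism and nutrition disorders
Hyperkalaemia	Metabolism and nutrition disorders
Hyperuricaemia	Metabolism and nutrition disorders
Hypocalcaemia	Metabolism and nutrition disorders
Hypokalaemia	Metabolism and nutrition disorders
Decreased appetite	Metabolism and nutrition disorders
Hypogammaglobulinaemia	Immune system disorders
Humoral immune defect	Immune system disorders
Cytokine release syndrome	Immune system disorders
Anaphylactic shock	Immune system disorders
Anaphylactoid reaction	Immune system disorders
Serum sickness	Immune system disorders
Secondary immunodeficiency	Immune system disorders
Immunodeficiency	Immune system disorders
Hypersensitivity	Immune system disorders
Infusion related reaction	Injury, poisoning and procedural complications
Tumour flare	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Tumour associated fever	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Malignant neoplasm progression	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Tumour pain	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Obliterative bronchiolitis	Respiratory, thoracic and mediastinal disorders
Dyspnoea	Respiratory, thoracic and mediastinal disorders
Cough	Respiratory, thoracic and mediastinal disorders
Hypoxia	Respiratory, thoracic and mediastinal disorders
Bronchospasm	Respiratory, thoracic and mediastinal disorders
Laryngeal oedema	Respiratory, thoracic and mediastinal disorders
Primary adrenal insufficiency	Endocrine disorders
Dermatitis acneiform	Skin and subcutaneous tissue disorders
Rash	Skin and subcutaneous tissue disorders
Pruritus	Skin and subcutaneous tissue disorders
Urticaria	Skin and subcutaneous tissue disorders
Hyperhidrosis	Skin and subcutaneous tissue disorders
Night sweats	Skin and subcutaneous tissue disorders
Pyrexia	General disorders and administration site conditions
Chills	General disorders and administration site conditions
Fatigue	General disorders and administration site conditions
Malaise	General disorders and administration site conditions
Asthenia	General disorders and administration site conditions
Oedema peripheral	General disorders and administration site conditions
Chest pain	General disorders and administration site conditions
Pain	General disorders and administration site conditions
Mucosal inflammation	General disorders and administration site conditions
Infusion site reaction	General disorders and administration site conditions
Drug ineffective	General disorders and administration site conditions
Death	General disorders and administration site conditions
Disease progression	General disorders and administration site conditions
Hypotension	Vascular disorders
Hypertension	Vascular disorders
Flushing	Vascular disorders
Atrial fibrillation	Cardiac disorders
Tachycardia	Cardiac disorders
Bradycardia	Cardiac disorders
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Constipation	Gastrointestinal disorders
Abdominal pain	Gastrointestinal disorders
Stomatitis	Gastrointestinal disorders
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Syncope	Nervous system disorders
Paraesthesia	Nervous system disorders
Neuropathy peripheral	Nervous system disorders
Dysgeusia	Nervous system disorders
Insomnia	Psychiatric disorders
Confusional state	Psychiatric disorders
Anxiety	Psychiatric disorders
Back pain	Musculoskeletal and connective tissue disorders
Arthralgia	Musculoskeletal and connective tissue disorders
Myalgia	Musculoskeletal and connective tissue disorders
Acute kidney injury	Renal and urinary disorders
Renal impairment	Renal and urinary disorders
Hepatotoxicity	Hepatobiliary disorders
Hepatic function abnormal	Hepatobiliary disorders
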