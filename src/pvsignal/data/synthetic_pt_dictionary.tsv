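verbatim_pt	current_pt	soc
CYTOKINE RELEASE SYNDROME	Cytokine release syndrome	Immune system disorders
CYTOKINE STORM	Cytokine storm	Immune system disorders
ICANS	Immune effector cell-associated neurotoxicity syndrome	Nervous system disorders
IMMUNE EFFECTOR CELL-ASSOCIATED NEUROTOXICITY SYNDROME	Immune effector cell-associated neurotoxicity syndrome	Nervous system disorders
NEUROTOXICITY	Neurotoxicity	Nervous system disorders
TREMOR	Tremor	Nervous system disorders
INTENTION TREMOR	Intention tremor	Nervous system disorders
HEADACHE	Headache	Nervous system disorders
PYREXIA	Pyrexia	General disorders and administration site conditions
FATIGUE	Fatigue	General disorders and administration site conditions
DRUG INEFFECTIVE	Drug ineffective	General disorders and administration site conditions
HYPOTENSION	Hypotension	Vascular disorders
CAPILLARY LEAK SYNDROME	Capillary leak syndrome	Vascular disorders
ORTHOSTATIC HYPOTENSION	Orthostatic hypotension	Vascular disorders
BACTERIAL INFECTION	Bacterial infection	Infections and infestations
VIRAL INFECTION	Viral infection	Infections and infestations
FUNGAL INFECTION	Fungal infection	Infections and infestations
SEPSIS	Sepsis	Infections and infestations
PLATELET COUNT DECREASED	Platelet count decreased	Investigations
WHITE BLOOD CELL COUNT DECREASED	White blood cell count decreased	Investigations
SERUM FERRITIN INCREASED	Serum ferritin increased	Investigations
HYPOXIA	Hypoxia	Respiratory, thoracic and mediastinal disorders
TACHYPNOEA	Tachypnoea	Respiratory, thoracic and mediastinal disorders
TACHYCARDIA	Tachycardia	Cardiac disorders
SINUS TACHYCARDIA	Sinus tachycardia	Cardiac disorders
HYPOGAMMAGLOBULINAEMIA	Hypogammaglobulinaemia	Immune system disorders
FEBRILE NEUTROPENIA	Febrile neutropenia	Blood and lymphatic system disorders
ACUTE KIDNEY FAILURE	Acute kidney injury	Renal and urinary disorders
ACUTE KIDNEY INJURY	Acute kidney injury	Renal and urinary disorders
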