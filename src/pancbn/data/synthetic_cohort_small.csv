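# synthetic fixture: 40 patients forward-sampled from the default post-operative network (seed 42); no real patient data
patient_id,mGPS,Neutrophil Lymphocyte Ratio,Albumin,Pre-treatment Ca19-9,CEA,Tumour Size,Tumour Location,T Stage,Jaundice,Age,Performance Status,Diabetes,Smoking,BMI,Pre-operative Blood Transfusion,Response to Neoadjuvant Treatment,Lymph Node Positive,Lymph Node Ratio,Tumour Grade,R0 Resection,AJCC Stage,Vascular Involvement,Perineural Invasion,Post-treatment Ca19-9,Adjuvant Therapy,survival_months,alive,resected
patient_00001,,,Low,<50,>5,>2cm,HOP,T3,Yes,>70,Poor,Yes,Smoker,Normal,,,,<0.3,G3/G4,No,3,Yes,Yes,,,7.554483527581573,False,True
patient_00002,0,,,<50,>5,>2cm,HOP,T4,No,>70,Moderate,Yes,,Low,No,Progression/Unresectable,No,<0.3,,Yes,3,No,Yes,<120,Yes,15.950906352008467,True,True
patient_00003,0,>5,Normal,,<5,>2cm,,T2,No,<70,Moderate,No,Non-smoker,Normal,No,Progression/Unresectable,Yes,,,Yes,3,No,No,>120,Yes,14.017037953533052,False,True
patient_00004,,<5,Low,>1000,<5,<2cm,HOP,T4,No,,Poor,Yes,,,Yes,Stable,Yes,<0.3,G3/G4,Yes,2,,,<120,Yes,3.132191953013499,False,True
patient_00005,0,<5,,,<5,>2cm,HOP,T4,,>70,Good,,Non-smoker,,Yes,,Yes,>0.3,G1/G2,Yes,1,No,No,,No,20.31159021921514,True,True
patient_00006,,<5,,<50,<5,>2cm,Body/Tail,T2,No,<70,Moderate,,Non-smoker,,Yes,Progression/Unresectable,No,<0.3,G3/G4,No,2,Yes,No,,,10.858851021240785,False,True
patient_00007,2,<5,Low,50-999,,>2cm,HOP,T4,Yes,,Good,Yes,Smoker,,No,,No,,G1/G2,,0,Yes,,,,28.175246092284027,True,True
patient_00008,0,<5,,50-999,>5,>2cm,Body/Tail,T1,Yes,,Good,Yes,Smoker,,,Stable,Yes,>0.3,G1/G2,No,3,Yes,No,>120,No,6.497272290498122,False,True
patient_00009,1,>5,,50-999,,<2cm,Body/Tail,T3,Yes,<70,Moderate,Yes,Smoker,Low,,Progression/Unresectable,,,,,,,,,,19.508714108141977,True,False
patient_00010,0,<5,Low,<50,>5,>2cm,HOP,T1,Yes,<70,,Yes,Non-smoker,Low,,Progression/Unresectable,,,,,,,,,,19.960176098178767,True,False
patient_00011,2,>5,Normal,>1000,,>2cm,HOP,T1,No,,Moderate,,,Normal,Yes,Progression/Unresectable,,,,,,,,,,6.12360309819713,False,False
patient_00012,0,<5,Normal,>1000,,>2cm,,T3,,>70,Moderate,Yes,Non-smoker,Normal,No,Progression/Unresectable,Yes,>0.3,G1/G2,Yes,4,No,Yes,>120,No,0.029039552844993377,False,True
patient_00013,2,<5,Normal,>1000,<5,,,T3,,<70,Poor,Yes,Non-smoker,Low,Yes,Progression/Unresectable,Yes,<0.3,G3/G4,Yes,1,No,Yes,,Yes,17.394594683608695,True,True
patient_00014,2,,,>1000,<5,<2cm,Body/Tail,T4,No,,,No,,Low,No,,,>0.3,G1/G2,,3,Yes,Yes,>120,Yes,11.062699283035634,False,True
patient_00015,0,>5,Low,50-999,<5,>2cm,Body/Tail,T3,No,,Moderate,Yes,Non-smoker,,Yes,Progression/Unresectable,,<0.3,G1/G2,No,0,No,No,>120,No,1.0490070702968257,False,True
patient_00016,2,,,>1000,<5,,HOP,T3,No,,Poor,,Non-smoker,Normal,Yes,Stable,,,,,,,,,,0.18517670099095085,False,False
patient_00017,2,>5,,,>5,<2cm,HOP,T3,Yes,>70,,No,Non-smoker,Normal,No,,No,<0.3,,No,1,Yes,No,<120,Yes,35.633939671098574,True,True
patient_00018,0,>5,Normal,50-999,<5,>2cm,HOP,T4,No,>70,,,Non-smoker,Low,Yes,,No,,G1/G2,No,4,Yes,,<120,,7.603974137321565,False,True
patient_00019,1,<5,Normal,50-999,>5,>2cm,HOP,T4,Yes,>70,,,Non-smoker,Low,No,,No,,G3/G4,No,,,No,>120,No,2.8489188964483114,False,True
patient_00020,0,,Low,,,<2cm,,,,<70,Moderate,,Non-smoker,Normal,,,Yes,<0.3,G3/G4,No,,No,Yes,>120,Yes,2.383326793887324,False,True
patient_00021,0,<5,Normal,50-999,<5,<2cm,HOP,T4,No,,,Yes,Smoker,Normal,,Stable,No,<0.3,G3/G4,,2,Yes,,>120,No,17.104286725821535,True,True
patient_00022,2,<5,Normal,<50,,>2cm,,,No,<70,Moderate,No,Smoker,Normal,Yes,Stable,No,<0.3,G3/G4,Yes,0,Yes,No,>120,Yes,6.016325437484218,False,True
patient_00023,2,>5,Low,50-999,<5,<2cm,,T1,Yes,<70,,Yes,Non-smoker,Normal,Yes,Progression/Unresectable,No,>0.3,G3/G4,,1,Yes,Yes,<120,Yes,8.755898541608069,False,True
patient_00024,1,,,<50,,>2cm,Body/Tail,T4,Yes,<70,,No,Smoker,,No,Stable,,,,,,,,,,51.54220763268437,True,False
patient_00025,,,,50-999,>5,<2cm,Body/Tail,T1,No,>70,Poor,Yes,Non-smoker,,No,Stable,Yes,>0.3,G1/G2,Yes,,Yes,Yes,>120,No,9.163674775397466,False,True
patient_00026,2,>5,Low,50-999,<5,<2cm,Body/Tail,,,<70,Moderate,No,Non-smoker,,No,,,<0.3,G1/G2,Yes,1,No,,<120,No,22.177888969871695,False,True
patient_00027,0,>5,Normal,,,<2cm,HOP,T4,No,<70,Moderate,,Non-smoker,Low,No,Stable,,,,,,,,,,4.637802183242014,False,False
patient_00028,2,<5,,>1000,>5,,Body/Tail,T4,No,,Good,Yes,Non-smoker,,,Stable,Yes,<0.3,G1/G2,No,4,Yes,No,>120,No,2.7378078812501374,False,True
patient_00029,0,>5,Normal,>1000,<5,>2cm,HOP,T2,No,<70,,No,Smoker,Normal,No,Stable,Yes,>0.3,G1/G2,Yes,3,Yes,,<120,No,2.880397395591239,False,True
patient_00030,1,<5,Normal,<50,<5,<2cm,HOP,,No,>70,Poor,Yes,Smoker,Low,Yes,Stable,,,,,,,,,,18.991737329337372,True,False
patient_00031,1,<5,,>1000,<5,>2cm,Body/Tail,T3,Yes,>70,Good,Yes,Smoker,Low,No,,Yes,<0.3,G3/G4,,1,Yes,,<120,No,21.0191231403274,False,True
patient_00032,0,>5,Low,50-999,<5,<2cm,HOP,T4,Yes,>70,Moderate,No,Non-smoker,Low,Yes,Stable,Yes,<0.3,G1/G2,No,3,No,Yes,<120,Yes,24.466582571841535,True,True
patient_00033,0,,,>1000,>5,,HOP,T3,Yes,>70,Moderate,Yes,Smoker,Normal,No,Stable,,,,,,,,,,25.317169293130625,True,False
patient_00034,2,<5,Normal,,>5,,HOP,T4,Yes,>70,Moderate,Yes,Non-smoker,Normal,,Stable,Yes,>0.3,G3/G4,Yes,0,No,Yes,<120,Yes,1.8025296263395663,False,True
patient_00035,,,Low,>1000,<5,<2cm,HOP,T1,No,,Good,Yes,Smoker,,Yes,Progression/Unresectable,,<0.3,G3/G4,Yes,4,No,No,>120,,26.37230537306463,True,True
patient_00036,2,>5,,<50,<5,<2cm,Body/Tail,T4,Yes,<70,Moderate,No,Non-smoker,Low,Yes,,No,,G3/G4,No,,Yes,No,<120,No,11.627164799161921,False,True
patient_00037,0,<5,Normal,<50,,<2cm,HOP,,Yes,,Good,No,Non-smoker,Low,,Stable,No,,G1/G2,Yes,3,No,No,<120,No,29.43532514078217,False,True
patient_00038,1,,Normal,>1000,>5,>2cm,,,No,>70,Good,No,Non-smoker,,,Progression/Unresectable,,,,,,,,,,10.575871595053862,False,False
patient_00039,1,<5,Normal,>1000,,<2cm,Body/Tail,T2,No,,Moderate,,Non-smoker,Normal,No,Progression/Unresectable,Yes,<0.3,G1/G2,No,4,,No,>120,Yes,47.87685909586781,True,True
patient_00040,1,,Normal,<50,<5,,,T1,,<70,Poor,No,,Low,No,Progression/Unresectable,Yes,<0.3,,Yes,3,No,Yes,>120,,26.743030572567466,True,True
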