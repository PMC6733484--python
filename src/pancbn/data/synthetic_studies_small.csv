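# synthetic fixture: 12 simulated studies x 6 variables (seed 42); no real study data
study_id,population,variable,status
study_001,135,Lymph Node Positive,included
study_001,135,Tumour Grade,significant
study_001,135,R0 Resection,excluded
study_001,135,Tumour Size,excluded
study_001,135,Age,excluded
study_001,135,Albumin,included
study_002,710,Lymph Node Positive,included
study_002,710,Tumour Grade,included
study_002,710,R0 Resection,significant
study_002,710,Tumour Size,significant
study_002,710,Age,excluded
study_002,710,Albumin,excluded
study_003,198,Lymph Node Positive,included
study_003,198,Tumour Grade,excluded
study_003,198,R0 Resection,significant
study_003,198,Tumour Size,significant
study_003,198,Age,included
study_003,198,Albumin,excluded
study_004,697,Lymph Node Positive,excluded
study_004,697,Tumour Grade,significant
study_004,697,R0 Resection,significant
study_004,697,Tumour Size,significant
study_004,697,Age,included
study_004,697,Albumin,included
study_005,589,Lymph Node Positive,included
study_005,589,Tumour Grade,excluded
study_005,589,R0 Resection,significant
study_005,589,Tumour Size,significant
study_005,589,Age,significant
study_005,589,Albumin,excluded
study_006,648,Lymph Node Positive,significant
study_006,648,Tumour Grade,significant
study_006,648,R0 Resection,significant
study_006,648,Tumour Size,included
study_006,648,Age,included
study_006,648,Albumin,excluded
study_007,543,Lymph Node Positive,significant
study_007,543,Tumour Grade,significant
study_007,543,R0 Resection,significant
study_007,543,Tumour Size,included
study_007,543,Age,significant
study_007,543,Albumin,included
study_008,593,Lymph Node Positive,significant
study_008,593,Tumour Grade,significant
study_008,593,R0 Resection,included
study_008,593,Tumour Size,significant
study_008,593,Age,included
study_008,593,Albumin,significant
study_009,817,Lymph Node Positive,significant
study_009,817,Tumour Grade,significant
study_009,817,R0 Resection,included
study_009,817,Tumour Size,significant
study_009,817,Age,included
study_009,817,Albumin,excluded
study_010,481,Lymph Node Positive,significant
study_010,481,Tumour Grade,excluded
study_010,481,R0 Resection,included
study_010,481,Tumour Size,significant
study_010,481,Age,included
study_010,481,Albumin,significant
study_011,666,Lymph Node Positive,significant
study_011,666,Tumour Grade,excluded
study_011,666,R0 Resection,included
study_011,666,Tumour Size,included
study_011,666,Age,included
study_011,666,Albumin,included
study_012,317,Lymph Node Positive,significant
study_012,317,Tumour Grade,significant
study_012,317,R0 Resection,significant
study_012,317,Tumour Size,included
study_012,317,Age,included
study_012,317,Albumin,excluded
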