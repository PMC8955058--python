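patient_id,sex,age_at_dx,cancer_type,dx_date,clinical_stage,pathological_stage,resection_date,adjuvant_flag
p01,male,68,gastric,2016-02-01,III,unknown,,
p02,female,54,breast,2016-03-15,II,unknown,,
p03,male,61,colorectal,2016-01-10,IV,unknown,,
p04,female,59,colorectal,2016-05-01,III,unknown,,
p05,male,70,non_small_cell_lung,2016-02-10,IV,unknown,,
p06,female,75,non_small_cell_lung,2016-06-01,IV,unknown,,
p07,male,72,gastric,2016-03-01,II,II,2016-03-10,true
p08,male,66,malignant_lymphoma,2016-02-20,III,unknown,,
p09,female,58,malignant_lymphoma,2016-01-15,II,unknown,,
p10,male,64,gastric,2016-04-01,III,unknown,,
p11,female,69,other,2016-03-01,IV,unknown,,
p12,male,47,malignant_lymphoma,2016-01-05,III,unknown,,
p13,female,19,other,2016-02-01,I,unknown,,
p14,female,62,breast,2016-07-01,I,unknown,,
p15,male,67,non_small_cell_lung,2016-01-20,IV,unknown,,
p16,female,63,pancreatic,2016-02-01,III,unknown,,
p17,male,71,pancreatic,2016-04-10,IV,unknown,,
p18,female,74,pancreatic,2016-03-05,IV,unknown,,
p19,male,65,oesophageal,2016-02-15,III,unknown,,
p20,male,60,oesophageal,2016-05-01,III,unknown,,
p21,male,69,small_cell_lung,2016-01-10,IV,unknown,,
p22,female,73,small_cell_lung,2016-03-01,IV,unknown,,
p23,male,77,malignant_lymphoma,2016-06-01,II,unknown,,
p24,female,49,breast,2016-08-01,I,unknown,,
p25,male,57,colorectal,2016-02-01,II,unknown,,
p26,female,55,other,2016-04-01,IV,unknown,,
p27,male,62,gastric,2016-01-15,III,unknown,,
p28,female,52,other,2016-02-01,III,unknown,,
p29,male,66,other,2016-05-10,II,unknown,,
p30,female,48,colorectal,2016-03-01,III,II,2016-04-01,true
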