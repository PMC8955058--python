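patient_id,date,drug_id,drug_class,route,dose_mg
p01,2016-03-01,s-1,chemotherapy,PO,120
p01,2016-03-04,s-1,chemotherapy,PO,120
p01,2016-03-08,s-1,chemotherapy,PO,120
p01,2016-03-08,cisplatin,chemotherapy,IV,89
p01,2016-03-08,aprepitant,NK1,PO,125
p01,2016-03-08,granisetron,serotonin_antagonist,IV,3
p01,2016-03-08,dexamethasone,steroid,IV,9.9
p02,2016-04-01,doxorubicin,chemotherapy,IV,89
p02,2016-04-01,cyclophosphamide,chemotherapy,IV,888
p02,2016-04-01,granisetron,serotonin_antagonist,IV,3
p02,2016-04-01,dexamethasone,steroid,IV,9.9
p03,2016-02-01,fluorouracil,chemotherapy,IV,2368
p03,2016-02-01,levofolinate,chemotherapy,IV,296
p03,2016-02-01,oxaliplatin,chemotherapy,IV,125
p03,2016-02-01,irinotecan,chemotherapy,IV,244
p03,2016-02-01,aprepitant,NK1,PO,125
p03,2016-02-01,granisetron,serotonin_antagonist,IV,3
p03,2016-02-01,dexamethasone,steroid,IV,9.9
p04,2016-05-20,fluorouracil,chemotherapy,IV,2960
p04,2016-05-20,levofolinate,chemotherapy,IV,296
p04,2016-05-20,oxaliplatin,chemotherapy,IV,125
p04,2016-05-20,granisetron,serotonin_antagonist,IV,3
p04,2016-05-20,dexamethasone,steroid,IV,9.9
p05,2016-03-01,carboplatin,chemotherapy,IV,600
p05,2016-03-01,paclitaxel,chemotherapy,IV,296
p05,2016-03-01,granisetron,serotonin_antagonist,IV,3
p05,2016-03-01,dexamethasone,steroid,IV,9.9
p05,2016-04-30,carboplatin,chemotherapy,IV,600
p05,2016-04-30,paclitaxel,chemotherapy,IV,296
p05,2016-04-30,aprepitant,NK1,PO,125
p06,2016-06-10,gefitinib,chemotherapy,PO,250
p06,2016-06-13,gefitinib,chemotherapy,PO,250
p06,2016-06-17,gefitinib,chemotherapy,PO,250
p07,2016-04-01,s-1,chemotherapy,PO,120
p07,2016-04-05,s-1,chemotherapy,PO,120
p07,2016-04-08,s-1,chemotherapy,PO,120
p07,2016-03-22,dexamethasone,steroid,PO,4
p08,2016-03-10,cyclophosphamide,chemotherapy,IV,1110
p08,2016-03-10,doxorubicin,chemotherapy,IV,74
p08,2016-03-10,vincristine,chemotherapy,IV,2
p08,2016-03-10,prednisolone,steroid,PO,100
p08,2016-03-12,prednisolone,steroid,PO,100
p08,2016-03-14,prednisolone,steroid,PO,100
p09,2016-02-01,interferon-alpha,chemotherapy,IV,9
p09,2016-02-01,cyclophosphamide,chemotherapy,IV,1110
p10,2016-05-01,cisplatin,chemotherapy,IV,118
p10,2016-05-01,granisetron,serotonin_antagonist,IV,3
p11,2016-04-01,cisplatin,chemotherapy,arterial,89
p12,2016-02-01,cyclophosphamide,chemotherapy,IV,2960
p13,2016-03-01,docetaxel,chemotherapy,IV,111
p14,2016-07-10,granisetron,serotonin_antagonist,IV,3
p15,2016-02-10,cisplatin,chemotherapy,IV,118
p15,2016-02-10,pemetrexed,chemotherapy,IV,740
p15,2016-02-10,aprepitant,NK1,PO,125
p15,2016-02-10,granisetron,serotonin_antagonist,IV,3
p16,2016-03-01,oxaliplatin,chemotherapy,IV,125
p16,2016-03-01,irinotecan,chemotherapy,IV,266
p16,2016-03-01,fluorouracil,chemotherapy,IV,2960
p16,2016-03-01,levofolinate,chemotherapy,IV,296
p16,2016-03-01,aprepitant,NK1,PO,125
p16,2016-03-01,granisetron,serotonin_antagonist,IV,3
p16,2016-03-01,dexamethasone,steroid,IV,9.9
p17,2016-05-01,gemcitabine,chemotherapy,IV,1480
p17,2016-05-01,nab-paclitaxel,chemotherapy,IV,185
p17,2016-05-08,gemcitabine,chemotherapy,IV,1480
p17,2016-05-08,nab-paclitaxel,chemotherapy,IV,185
p17,2016-05-01,granisetron,serotonin_antagonist,IV,3
p17,2016-05-01,dexamethasone,steroid,IV,9.9
p18,2016-04-01,gemcitabine,chemotherapy,IV,1480
p18,2016-04-08,gemcitabine,chemotherapy,IV,1480
p18,2016-04-01,dexamethasone,steroid,IV,4
p19,2016-03-01,fluorouracil,chemotherapy,IV,1184
p19,2016-03-01,cisplatin,chemotherapy,IV,118
p19,2016-03-01,aprepitant,NK1,PO,125
p19,2016-03-01,granisetron,serotonin_antagonist,IV,3
p19,2016-03-01,dexamethasone,steroid,IV,9.9
p20,2016-06-01,docetaxel,chemotherapy,IV,104
p20,2016-06-01,cisplatin,chemotherapy,IV,104
p20,2016-06-01,fluorouracil,chemotherapy,IV,1110
p20,2016-06-01,aprepitant,NK1,PO,125
p20,2016-06-01,granisetron,serotonin_antagonist,IV,3
p20,2016-06-01,dexamethasone,steroid,IV,9.9
p21,2016-02-01,cisplatin,chemotherapy,IV,118
p21,2016-02-01,etoposide,chemotherapy,IV,148
p21,2016-02-02,etoposide,chemotherapy,IV,148
p21,2016-02-03,etoposide,chemotherapy,IV,148
p21,2016-02-01,aprepitant,NK1,PO,125
p21,2016-02-01,granisetron,serotonin_antagonist,IV,3
p21,2016-02-01,dexamethasone,steroid,IV,9.9
p22,2016-04-01,carboplatin,chemotherapy,IV,625
p22,2016-04-01,etoposide,chemotherapy,IV,148
p22,2016-04-02,etoposide,chemotherapy,IV,148
p22,2016-04-03,etoposide,chemotherapy,IV,148
p22,2016-04-01,granisetron,serotonin_antagonist,IV,3
p22,2016-04-01,dexamethasone,steroid,IV,9.9
p23,2016-07-01,etoposide,chemotherapy,PO,50
p23,2016-07-04,etoposide,chemotherapy,PO,50
p23,2016-07-08,etoposide,chemotherapy,PO,50
p23,2016-07-01,granisetron,serotonin_antagonist,IV,3
p24,2016-09-01,trastuzumab,chemotherapy,IV,296
p25,2016-03-01,capecitabine,chemotherapy,PO,2960
p25,2016-03-04,capecitabine,chemotherapy,PO,2960
p25,2016-03-08,capecitabine,chemotherapy,PO,2960
p26,2016-05-01,investigational-x,chemotherapy,IV,
p27,2016-02-01,s-1,chemotherapy,PO,120
p27,2016-02-04,s-1,chemotherapy,PO,120
p27,2016-02-08,s-1,chemotherapy,PO,120
p27,2016-02-08,cisplatin,chemotherapy,IV,89
p27,2016-02-01,aprepitant,NK1,PO,125
p27,2016-02-01,granisetron,serotonin_antagonist,IV,3
p27,2016-02-01,dexamethasone,steroid,IV,9.9
p28,2016-03-01,cisplatin,chemotherapy,IV,118
p28,2016-03-01,granisetron,serotonin_antagonist,IV,3
p28,2016-03-01,dexamethasone,steroid,IV,9.9
p29,2016-06-01,carboplatin,chemotherapy,IV,600
p29,2016-06-10,granisetron,serotonin_antagonist,IV,3
p30,2016-05-01,paclitaxel,chemotherapy,IV,133
p30,2016-05-01,dexamethasone,steroid,IV,8
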