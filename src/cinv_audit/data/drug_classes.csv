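raw_name,drug_id,drug_class
5-fluorouracil,fluorouracil,chemotherapy
5-fu,fluorouracil,chemotherapy
adm,doxorubicin,chemotherapy
afatinib,afatinib,chemotherapy
aprepitant,aprepitant,NK1
azasetron,azasetron,serotonin_antagonist
betamethasone,betamethasone,steroid
bortezomib,bortezomib,chemotherapy
capecitabine,capecitabine,chemotherapy
carboplatin,carboplatin,chemotherapy
cbdca,carboplatin,chemotherapy
cddp,cisplatin,chemotherapy
cetuximab,cetuximab,chemotherapy
cisplatin,cisplatin,chemotherapy
cpa,cyclophosphamide,chemotherapy
cpm,cyclophosphamide,chemotherapy
cpt-11,irinotecan,chemotherapy
cpt11,irinotecan,chemotherapy
cyclophosphamide,cyclophosphamide,chemotherapy
cytarabine,cytarabine,chemotherapy
dasatinib,dasatinib,chemotherapy
dexamethasone,dexamethasone,steroid
docetaxel,docetaxel,chemotherapy
doxorubicin,doxorubicin,chemotherapy
dtx,docetaxel,chemotherapy
epi,epirubicin,chemotherapy
epirubicin,epirubicin,chemotherapy
erlotinib,erlotinib,chemotherapy
etoposide,etoposide,chemotherapy
fluorouracil,fluorouracil,chemotherapy
folinate,folinate,chemotherapy
fosaprepitant,fosaprepitant,NK1
gefitinib,gefitinib,chemotherapy
gem,gemcitabine,chemotherapy
gemcitabine,gemcitabine,chemotherapy
granisetron,granisetron,serotonin_antagonist
hydrocortisone,hydrocortisone,steroid
hydroxycarbamide,hydroxycarbamide,chemotherapy
ifosfamide,ifosfamide,chemotherapy
imatinib,imatinib,chemotherapy
interferon-alfa,interferon-alpha,chemotherapy
interferon-alpha,interferon-alpha,chemotherapy
irinotecan,irinotecan,chemotherapy
l-lv,levofolinate,chemotherapy
l-ohp,oxaliplatin,chemotherapy
lenalidomide,lenalidomide,chemotherapy
levofolinate,levofolinate,chemotherapy
lv,folinate,chemotherapy
methotrexate,methotrexate,chemotherapy
methylprednisolone,methylprednisolone,steroid
mitomycin-c,mitomycin-c,chemotherapy
nab-paclitaxel,nab-paclitaxel,chemotherapy
nedaplatin,nedaplatin,chemotherapy
nelarabine,nelarabine,chemotherapy
nimustine,nimustine,chemotherapy
nivolumab,nivolumab,chemotherapy
ondansetron,ondansetron,serotonin_antagonist
oxaliplatin,oxaliplatin,chemotherapy
paclitaxel,paclitaxel,chemotherapy
palonosetron,palonosetron,serotonin_antagonist
panitumumab,panitumumab,chemotherapy
pemetrexed,pemetrexed,chemotherapy
pertuzumab,pertuzumab,chemotherapy
prednisolone,prednisolone,steroid
procarbazine,procarbazine,chemotherapy
psl,prednisolone,steroid
ptx,paclitaxel,chemotherapy
ramosetron,ramosetron,serotonin_antagonist
ramucirumab,ramucirumab,chemotherapy
ranimustine,ranimustine,chemotherapy
regorafenib,regorafenib,chemotherapy
rituximab,rituximab,chemotherapy
s-1,s-1,chemotherapy
s1,s-1,chemotherapy
sorafenib,sorafenib,chemotherapy
sunitinib,sunitinib,chemotherapy
tegafur-uracil,tegafur-uracil,chemotherapy
temozolomide,temozolomide,chemotherapy
trastuzumab,trastuzumab,chemotherapy
uft,tegafur-uracil,chemotherapy
vcr,vincristine,chemotherapy
vincristine,vincristine,chemotherapy
vinorelbine,vinorelbine,chemotherapy
vnr,vinorelbine,chemotherapy
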