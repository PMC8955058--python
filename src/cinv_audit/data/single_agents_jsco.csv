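drug_id,route,tier_bound,bound_op,bound_unit,category,missing_dose_category
cisplatin,IV,,,,high,
procarbazine,PO,,,,high,
oxaliplatin,IV,,,,moderate,
nedaplatin,IV,,,,moderate,
temozolomide,PO,,,,moderate,
imatinib,PO,,,,moderate,
cyclophosphamide,PO,,,,moderate,
gemcitabine,IV,,,,low,
docetaxel,IV,,,,low,
paclitaxel,IV,,,,low,
nab-paclitaxel,IV,,,,low,
mitomycin-c,IV,,,,low,
fluorouracil,IV,,,,low,
pemetrexed,IV,,,,low,
etoposide,IV,,,,low,
etoposide,PO,,,,low,
irinotecan,IV,,,,low,
vinorelbine,IV,,,,low,
s-1,PO,,,,low,
tegafur-uracil,PO,,,,low,
capecitabine,PO,,,,low,
lenalidomide,PO,,,,low,
afatinib,PO,,,,low,
dasatinib,PO,,,,low,
sunitinib,PO,,,,low,
rituximab,IV,,,,minimal,
trastuzumab,IV,,,,minimal,
nivolumab,IV,,,,minimal,
ramucirumab,IV,,,,minimal,
vincristine,IV,,,,minimal,
levofolinate,IV,,,,minimal,
folinate,PO,,,,minimal,
gefitinib,PO,,,,minimal,
erlotinib,PO,,,,minimal,
sorafenib,PO,,,,minimal,
regorafenib,PO,,,,minimal,
hydroxycarbamide,PO,,,,minimal,
methotrexate,PO,,,,minimal,
cyclophosphamide,IV,1500,gt,mg_m2,high,moderate
cyclophosphamide,IV,,,,moderate,moderate
methotrexate,IV,250,gt,mg_m2,high,moderate
methotrexate,IV,50,ge,mg_m2,moderate,moderate
methotrexate,IV,,,,low,moderate
cytarabine,IV,200,gt,mg_m2,moderate,moderate
cytarabine,IV,,,,low,moderate
carboplatin,IV,,,,moderate,
doxorubicin,IV,,,,moderate,
epirubicin,IV,,,,moderate,
ifosfamide,IV,,,,moderate,
bortezomib,IV,,,,minimal,
cetuximab,IV,,,,minimal,
nelarabine,IV,,,,minimal,
panitumumab,IV,,,,minimal,
pertuzumab,IV,,,,minimal,
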