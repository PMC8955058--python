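guideline,name,components,cancer_context,category,single_agent_override
JSCO,FOLFOXIRI,fluorouracil|levofolinate|oxaliplatin|irinotecan,colorectal,high,false
JSCO,FOLFIRINOX,fluorouracil|levofolinate|oxaliplatin|irinotecan,pancreatic,high,false
JSCO,GS,gemcitabine|s-1,pancreatic,moderate,false
JSCO,GEM+nab-PTX,gemcitabine|nab-paclitaxel,pancreatic,moderate,false
JSCO,ICE,ifosfamide|carboplatin|etoposide,malignant_lymphoma,high,false
JSCO,AC,doxorubicin:IV|cyclophosphamide:IV,,high,false
JSCO,EC,epirubicin:IV|cyclophosphamide:IV,,high,false
JSCO,oral etoposide,etoposide:PO,malignant_lymphoma,moderate,true
JSCO,nimustine,nimustine,malignant_lymphoma,moderate,true
JSCO,ranimustine,ranimustine,malignant_lymphoma,moderate,true
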