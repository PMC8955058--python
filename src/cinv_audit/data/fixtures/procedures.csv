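patient_id,date,kind
p07,2016-03-10,surgery
p10,2016-05-01,surgery
p12,2016-02-15,hsct
p28,2016-03-23,hsct
p30,2016-04-01,surgery
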