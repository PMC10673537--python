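# table_version: cdc-oral-v1
drug,factor,is_opioid,synonyms,schedule,tier_max_mg,tier_factor
morphine,1.0,true,ms contin|kadian|avinza,II,,
codeine,0.15,true,tylenol #3|tylenol #4|codeine-acetaminophen,II,,
tramadol,0.1,true,ultram|conzip,IV,,
hydrocodone,1.0,true,norco|vicodin|lortab|hydrocodone-acetaminophen,II,,
oxycodone,1.5,true,oxycontin|percocet|roxicodone|oxycodone-acetaminophen,II,,
hydromorphone,4.0,true,dilaudid|exalgo,II,,
oxymorphone,3.0,true,opana,II,,
tapentadol,0.4,true,nucynta,II,,
fentanyl patch,2.4,true,duragesic|fentanyl transdermal,II,,
methadone,,true,dolophine|methadose,II,20,4.0
methadone,,true,dolophine|methadose,II,40,8.0
methadone,,true,dolophine|methadose,II,60,10.0
methadone,,true,dolophine|methadose,II,inf,12.0
acetaminophen,0,false,tylenol|paracetamol,,,
ibuprofen,0,false,advil|motrin,,,
naproxen,0,false,aleve|naprosyn,,,
aspirin,0,false,,,,
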