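center_id,year,month,patient_status,tumor_group,sex,stage,count
network,2019,1,new,all,all,all,7069
network,2019,2,new,all,all,all,6384
network,2019,3,new,all,all,all,6736
network,2019,4,new,all,all,all,6673
network,2019,5,new,all,all,all,6672
network,2019,6,new,all,all,all,6319
network,2019,7,new,all,all,all,7306
network,2020,1,new,all,all,all,7378
network,2020,2,new,all,all,all,6725
network,2020,3,new,all,all,all,6645
network,2020,4,new,all,all,all,5296
network,2020,5,new,all,all,all,5218
network,2020,6,new,all,all,all,6208
network,2020,7,new,all,all,all,6477
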