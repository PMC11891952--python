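condition,image,measure,manual,automated
control,1,apoptotic,5,5
control,1,necrotic,5,3
control,1,viable,308,316
control,2,apoptotic,2,1
control,2,necrotic,1,1
control,2,viable,400,404
control,3,apoptotic,11,9
control,3,necrotic,9,7
control,3,viable,425,424
treatment,1,apoptotic,59,50
treatment,1,necrotic,88,110
treatment,1,viable,0,8
treatment,2,apoptotic,19,19
treatment,2,necrotic,65,65
treatment,2,viable,3,6
treatment,3,apoptotic,51,51
treatment,3,necrotic,259,264
treatment,3,viable,15,15
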