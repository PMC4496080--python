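sample_id,species,port,total_length_cm,weight_kg,weight_estimated,otolith_excluded
BR1,dourada,Belem,75,8.00,false,false
BR3,dourada,Belem,75,8.00,false,false
BR6,dourada,Belem,75,8.00,false,false
BR7,dourada,Belem,75,8.00,false,false
BR8,dourada,Belem,75,8.00,false,false
BR10,dourada,Belem,75,8.00,false,false
BR12,dourada,Belem,75,8.00,false,false
BR14,dourada,Belem,75,8.00,false,false
BR16,dourada,Belem,75,8.00,false,false
BR18,dourada,Belem,100,22.00,false,false
BR19,dourada,Manaus,110,11.00,false,false
BR21,dourada,Manaus,100,6.00,false,false
BR23,dourada,Manaus,115,10.00,false,false
BR24,dourada,Manaus,75,3.70,false,false
BR25,dourada,Manaus,80,4.00,false,false
BR26,dourada,Manaus,,,false,true
BV1,piramutaba,Manaus,75,4.19,true,false
BV2,piramutaba,Manaus,70,3.38,true,false
BV3,piramutaba,Manaus,68,3.09,true,false
BV4,piramutaba,Manaus,65,2.68,true,false
BV5,piramutaba,Manaus,70,3.38,true,false
BF1,piraiba,Belem,220,110.00,false,false
BF3,piraiba,Belem,250,130.00,false,false
BF5,piraiba,Belem,90,20.00,false,false
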