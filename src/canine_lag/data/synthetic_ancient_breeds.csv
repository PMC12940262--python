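breed,label,weight_kg,lifespan_yr,litter_size,cancer_deaths,diagnosed_deaths
basenji,ancient,10.5,13.0,5.0,20,120
tibetan_mastiff,ancient,50.0,11.5,6.5,25,110
jindo,ancient,18.0,13.5,5.5,22,130
chow_chow,ancient,25.0,12.0,5.0,30,140
dingo,ancient,16.0,13.0,5.0,18,100
new_guinea_singing_dog,ancient,11.0,14.0,4.5,15,90
greenland_sledge_dog,ancient,30.0,12.5,6.0,28,125
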