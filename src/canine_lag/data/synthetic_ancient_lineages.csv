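child,parent,divergence_time_years
dogs,,16000
basenji,dogs,0
holarctic,dogs,9500
greenland_sledge_dog,holarctic,0
eurasian,holarctic,8500
oceanian,eurasian,5000
dingo,oceanian,0
new_guinea_singing_dog,oceanian,0
mainland,eurasian,3000
asian,mainland,500
tibetan_mastiff,asian,0
jindo,asian,0
chow_chow,asian,0
modern,mainland,200
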