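name,min_age,max_age,obs_days_nonmusth,obs_days_musth,total_days_nonmusth,total_days_musth
Bahati/Nusura,20,20,2,1,4,3
Kiir,21,22,3,1,9,3
Ansel,22,24,25,0,60,0
Columbus,26,27,35,0,86,0
Lemaiyan,27,27,1,1,3,3
Nehru,28,29,9,1,25,3
Thoreau,23,31,5,1,13,3
Picasso,31,32,9,3,25,5
Edison,29,33,7,17,19,37
Frank,33,33,1,8,2,21
Uffe,21,34,28,3,77,14
Winston,28,34,89,19,221,47
Theresai,33,34,7,3,20,7
Boru,32,37,4,1,14,3
Nelson Mandela,36,37,12,0,28,0
MLK,37,37,2,3,4,10
Apollo,36,38,56,20,131,51
Boone,39,39,3,6,9,13
Leakey,40,41,2,0,3,2
Lewis,41,41,7,0,18,0
Esidai,35,44,80,30,217,75
Kenyatta,42,44,52,21,136,44
PrettyBomBom,44,45,33,32,92,80
Mungu,46,48,64,22,153,51
Matt,39,52,2,6,6,21
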