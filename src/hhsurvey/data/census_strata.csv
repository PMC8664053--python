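municipality,sex,age_group,N
Teresina,M,0-2,16652
Teresina,M,3-4,11373
Teresina,M,5-9,29010
Teresina,M,10-14,33404
Teresina,M,15-19,33807
Teresina,M,20-59,206062
Teresina,M,60+,26299
Teresina,F,0-2,16085
Teresina,F,3-4,10905
Teresina,F,5-9,28073
Teresina,F,10-14,32820
Teresina,F,15-19,36003
Teresina,F,20-59,248680
Teresina,F,60+,38384
Picos,M,0-2,1187
Picos,M,3-4,848
Picos,M,5-9,2237
Picos,M,10-14,2598
Picos,M,15-19,2689
Picos,M,20-59,15600
Picos,M,60+,2263
Picos,F,0-2,1258
Picos,F,3-4,820
Picos,F,5-9,2201
Picos,F,10-14,2522
Picos,F,15-19,2824
Picos,F,20-59,18144
Picos,F,60+,3130
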