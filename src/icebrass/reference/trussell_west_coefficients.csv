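i,age_group,a,b,c
1,15-19,1.1415,-2.7070,0.7663
2,20-24,1.2563,-0.5381,-0.2637
3,25-29,1.1851,0.0633,-0.4177
4,30-34,1.1720,0.2341,-0.4272
5,35-39,1.1865,0.3080,-0.4452
6,40-44,1.1746,0.3314,-0.4537
7,45-49,1.1639,0.3190,-0.4435
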