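basket,label,n,y,q0,q1
1,NSCLC,20,8,0.15,0.45
2,Colorectal cancer,10,0,0.15,0.45
3,Cholangiocarcinoma,8,1,0.15,0.45
4,ECD/LCH,18,6,0.15,0.45
5,Thyroid cancer,7,2,0.15,0.45
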