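feature,alpha,beta,gamma,delta,theta
hurst,0.7778,0.7624,0.7997,0.6175,0.7037
fluctuation,0.8134,0.8878,0.7959,0.7602,0.8178
sampen,0.7190,0.6530,0.5368,0.6091,0.5392
permen,0.7327,0.6490,0.5997,0.7204,0.5914
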