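index,svm,linear_svm,rbfnn,rf,elm,ielm
accuracy,0.6275,0.6598,0.7609,0.7567,0.7912,0.8728
recall,0.6515,0.6702,0.7122,0.6547,0.7687,0.8913
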