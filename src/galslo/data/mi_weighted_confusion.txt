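# Worked-example confusion matrix: myocardial-infarction vs healthy-control test
# split, solution [5,1,0,1,0,0,1,0,1,0,1,0,1], weighted cross-entropy training.
HC MI
391 28
22 1663
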