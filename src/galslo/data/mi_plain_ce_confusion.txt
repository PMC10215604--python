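# Worked-example confusion matrix: same MI task and solution as
# mi_weighted_confusion.txt but trained with plain (unweighted) cross-entropy.
HC MI
356 63
19 1666
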