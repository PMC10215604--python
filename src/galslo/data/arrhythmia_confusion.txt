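# Worked-example confusion matrix: 5-class arrhythmia test split,
# solution [9,1,1,0,1,1,0,1,1,0,1,0,0] (9 s segments, leads I,II,avR,avL,V1,V2,V4).
# Rows: true class; columns: predicted class.
N PAC T B PVC
998 0 0 0 0
1 655 0 0 5
0 0 429 0 0
0 1 0 332 0
5 12 0 0 279
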