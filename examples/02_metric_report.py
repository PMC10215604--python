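"""Render the per-class + macro metric table for a confusion matrix.

Feeds the bundled worked-example arrhythmia confusion matrix (5 classes,
2717 test segments) through the metrics module. Each row is one-vs-rest
sensitivity / specificity / positive predictivity / accuracy / F1 in
percent; the Average row is the unweighted macro mean of the unrounded
per-class values, rounded half-up at two decimals for display.
"""

import importlib.resources

from galslo.metrics import macro_report, read_confusion_grid

path = importlib.resources.files("galslo") / "data" / "arrhythmia_confusion.txt"
cm = read_confusion_grid(path)
print("confusion matrix (rows true, columns predicted):")
print(cm.to_frame(), end="\n\n")
print(macro_report(cm).to_text())
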