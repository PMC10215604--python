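"""End-to-end run: records -> denoise/segment -> per-lead CNN features ->
GA search -> held-out report.

Uses a reduced-width feature extractor (1/16 of the full stage widths,
identical topology) on a small synthetic two-class set whose morphology
difference is planted on leads II and avR. Takes roughly two minutes on one
CPU; the final table is computed on patients never seen in training.
"""

import logging

from galslo.pipeline import RunConfig, run_full
from galslo.synthetic import mi_synth_config

logging.basicConfig(level=logging.INFO, format="%(message)s")

cfg = RunConfig(
    task="mi",
    synth=mi_synth_config(effect=1.5, n_patients_per_class=8,
                          record_seconds=(20.0, 40.0), seed=11,
                          informative_leads=(2, 4)),
    lengths=(1, 2), leads=tuple(range(1, 13)),
    width_scale=1 / 16, fem_epochs=10,
    head="lam", loss="weighted_ce",
    head_kwargs={"epochs": 20, "hidden": (32,)},
    max_segments_per_record=15,
    seed=11,
)
result = run_full(cfg)

T_L, leads = result.best.chromosome.decode()
print(f"\nbest chromosome: [{result.best.chromosome}]")
print(f"decoded: {T_L} s segments, leads {', '.join(leads)}")
print(f"search fitness: {result.best.fitness:.4f}\n")
print("held-out test report (percent):")
print(result.report.to_text())
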