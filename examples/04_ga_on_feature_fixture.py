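"""Genetic search on a planted feature fixture, checked against brute force.

Builds class-conditional Gaussian features for 4 leads x 3 segment lengths
where only leads 2 and 4 carry class signal, then runs the GA and compares
its answer with exhaustive enumeration of all 45 valid chromosomes.
Runs in a few seconds.
"""

from galslo.ga import Evaluator, GaConfig, enumerate_space, evolve, \
    exhaustive_search
from galslo.synthetic import FeatureFixtureConfig, generate_feature_fixture

cfg = FeatureFixtureConfig(lengths=(1, 2, 3), leads=(1, 2, 3, 4),
                           informative_leads=(2, 4), feature_width=64,
                           n_train_patients=6, n_test_patients=3,
                           segments_per_patient=4, seed=1)
cache = generate_feature_fixture(cfg)
evaluator = Evaluator(cache, head="mlp", seed=1,
                      head_kwargs={"epochs": 15, "hidden": (32,)})
ga_cfg = GaConfig(lengths=(1, 2, 3), leads=(1, 2, 3, 4), seed=3)

best, history = evolve(evaluator, ga_cfg)
optimum = exhaustive_search(evaluator, ga_cfg)

print(f"search space: {len(enumerate_space(ga_cfg))} chromosomes")
print(f"GA best:      [{best.chromosome}]  fitness {best.fitness:.4f} "
      f"(F1 {best.f1:.3f}, Acc {best.acc:.3f})")
print(f"exhaustive:   [{optimum.chromosome}]  fitness {optimum.fitness:.4f}")
print(f"generations run: {len(history)} (early stop after 3 stalled generations)")
print(f"heads trained: {evaluator.n_trainings} (memoized re-evaluations are free)")
T_L, leads = best.chromosome.decode()
print(f"decoded: {T_L} s segments, leads {', '.join(leads)} - drawn from the "
      f"planted informative set; the 0.01/lead penalty trims leads that add "
      f"no accuracy")
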