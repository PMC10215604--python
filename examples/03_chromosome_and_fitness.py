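"""The chromosome encoding and the complexity-penalised fitness.

A candidate solution is C = [T_L, L_1..L_12]: segment length in seconds plus
a binary mask over the canonical leads. Fitness rewards macro-F1 and
accuracy and charges 0.002 per second of input and 0.01 per lead.
"""

from galslo.ga import Chromosome, fitness

for vec in ("3,0,1,0,1,0,0,0,0,1,1,0,0",
            "9,1,1,0,1,1,0,1,1,0,1,0,0",
            "5,1,0,1,0,0,1,0,1,0,1,0,1"):
    c = Chromosome.from_vector(vec.split(","))
    T_L, leads = c.decode()
    f = fitness(1.0, 1.0, c)
    print(f"[{c}] -> {T_L} s, leads {', '.join(leads)}; "
          f"fitness at perfect F1/Acc = {f:.3f}")

print("\nthe penalty orders equally-accurate solutions by complexity:")
lean = Chromosome.from_vector("1,0,1,0,1,0,0,0,0,0,0,0,0".split(","))
fat = Chromosome.from_vector("9,1,1,1,1,1,1,1,1,1,1,1,1".split(","))
print(f"  2 leads @ 1 s: {fitness(0.95, 0.95, lean):.3f}")
print(f"  12 leads @ 9 s: {fitness(0.95, 0.95, fat):.3f}")
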