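"""When the difference test does not apply.

The delta-T comparison requires one model's vanishing-tetrad set to be a
strict subset of the other's.  Two failure modes are demonstrated: models
with identical vanishing sets (equivalent by tetrads) and models whose
sets are not nested at all (the offending tetrads are reported).
"""

import gscata as g

cfg = g.builtin_config("M3", n=2000, seed=19)
data = g.standardize(g.generate(cfg, clip=False))

# M0 (correlated factors) and M1 (directed path) share the measurement
# structure, so their implied vanishing sets coincide
try:
    g.compare_models(data, g.builtin_model("M0"), g.builtin_model("M1"))
except g.TetradEquivalenceError as exc:
    print("M0 vs M1:", exc)

# reversing the roles: the two-factor model's 138 vanishing tetrads are
# not a subset of the four-factor model's 54
try:
    g.compare_models(data, g.builtin_model("M3"), g.builtin_model("M0"))
except g.NotNestedError as exc:
    print(f"M3 (as restrictive) vs M0: not nested, "
          f"{exc.offending.size} offending tetrads, e.g. indices "
          f"{exc.offending[:5].tolist()}")
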