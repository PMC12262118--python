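"""Day-wise mixed-effects inference on component amplitudes.

Fits amplitude ~ day (categorical, day 1 the reference) with by-participant
random intercepts and day slopes by maximum likelihood; p-values use
Satterthwaite-approximated degrees of freedom.
"""

import numpy as np

import erplearn as el

rng = np.random.default_rng(4)
true_day_effects = (0.0, 0.15, 0.28, 0.72)  # uV relative to day 1

measures = []
for p in range(14):
    b0 = rng.normal(0, 0.8)           # stable participant offset
    bs = rng.normal(0, 0.25, 4)       # participant-specific day slopes
    bs[0] = 0.0
    for d in range(4):
        amp = -2.0 + true_day_effects[d] + b0 + bs[d] + rng.normal(0, 0.2)
        measures.append(el.ComponentMeasure(
            f"sub-{p + 1:02d}", d + 1, "dev_large", "MMN", amp, 220.0))

table = el.build_measure_table(measures)
fit = el.fit_lmm(table, "amplitude", "MMN", "dev_large")

print(f"random-effects structure used: {fit.structure}")
print(f"{'effect':<10}{'estimate':>9}{'SE':>7}{'t':>8}{'df':>7}{'p':>9}")
for e in fit.effects:
    print(f"{e.name:<10}{e.estimate:>9.3f}{e.se:>7.3f}{e.t:>8.2f}"
          f"{e.df:>7.1f}{e.p:>9.4f}")
print(f"\nprogrammed day effects: {true_day_effects[1:]} uV")
# Each day-k estimate is the amplitude change relative to day 1 after
# absorbing between-participant variability into the random effects; with
# 14 participants the day-4 effect (0.72 uV) should be clearly significant
# while the small day-2 effect (0.15 uV) typically is not.
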