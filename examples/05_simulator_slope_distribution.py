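"""Effect of coupling strength on the correlation-vs-distance slope.

Repeats the tissue simulation at coupling strengths delta = 0 and 0.5 and
compares the distributions of median-regression slopes (correlation of mRNA
series against normalised Euclidean distance).  Coupling shifts the
distribution negative; without it the slopes centre on zero.
"""

import numpy as np
from scipy.stats import mannwhitneyu

from tissuecorr import simulator

N_REPS = 15  # scaled for a quick demonstration

slopes = {}
for delta in (0.0, 0.5):
    params = simulator.SimParams(delta=delta, delta_b=0.0)
    df = simulator.slope_experiment(params, n_reps=N_REPS, seed=42)
    sub = df[(df.level == "mrna") & (df.range == "short")]
    slopes[delta] = sub.slope.to_numpy()
    print(f"delta={delta}: median short-range slope {np.median(slopes[delta]):+.4f}, "
          f"negative in {(slopes[delta] < 0).mean():.0%} of replicates")

p = mannwhitneyu(slopes[0.5], slopes[0.0], alternative="less").pvalue
print(f"one-sided rank test (coupled < uncoupled): p = {p:.2e}")
# A small p confirms that contact coupling, not chance, produces the
# negative distance trend.
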