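"""The LBA race density, piece by piece.

Evaluates the single-accumulator first-passage CDF/PDF, the four-way race
defective density, and the contaminant-mixture trial likelihood for one
parameter set, and cross-checks the race's choice probabilities against
quadrature.  The four masses sum to the probability that any accumulator
finishes (slightly below 1); each divided by that total is the model's
predicted response share.
"""

import numpy as np
from scipy.integrate import quad

from lbaspeech import (IndividualParams, TrialContext, accumulator_cdf,
                       accumulator_pdf, race_defective_log_density,
                       trial_log_likelihood)
from lbaspeech.lba import RESPONSES

drifts = np.array([2.0, 0.5, 0.4, 0.3])  # correct, semantic, phonetic, neither
A, b, t0 = 0.8, 1.3, 0.3

print("single accumulator (v=2, A=0.8, b=1.3):")
for t in (0.25, 0.5, 1.0, 3.0):
    print(f"  t={t:4.2f}s  F={accumulator_cdf(t, A, b, 2.0):.4f}"
          f"  f={accumulator_pdf(t, A, b, 2.0):.4f}")

print("\nrace choice probabilities (quadrature over the defective density):")
masses = [quad(lambda t: np.exp(race_defective_log_density(t, r, drifts, A, b)),
               0, np.inf, limit=200)[0] for r in range(4)]
for r, m in zip(RESPONSES, masses):
    print(f"  {r:<9} {m:.4f}")
print(f"  total (P(any finishes)) = {sum(masses):.4f}")

params = IndividualParams(v=np.tile(drifts, (3, 1)), boost_kw2=0.4,
                          boost_kw3=0.6, A=A, b=b, t0=t0)
ctx = TrialContext(mode="audio", keyword_index=2, kw1_correct=True)
ll = trial_log_likelihood(1.1, 0, params, ctx, lam=0.02, t_max=10.0)
print(f"\nmixture log likelihood of a correct keyword-2 response at 1.1 s")
print(f"(boosted drift {drifts[0]}+0.4, 2% lapse mixture): {ll:.4f}")
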