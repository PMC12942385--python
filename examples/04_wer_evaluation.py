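"""Word error rate of a noisy recogniser against ground truth.

The mock recogniser corrupts each spoken token with a 10% substitution
rate (confusable optotype letters). WER = 100 x (S + I + D) / N from a
minimum edit-distance alignment, so with substitution-only noise the
measured WER estimates the substitution rate.
"""

import numpy as np

from autova import ChartSpec, ConfusionSpec, MockRecognizer, wer

chart = ChartSpec.default()
conf = ConfusionSpec(sub_rate=0.10, confusions={s: [t for t in chart.vocab if t != s] for s in chart.vocab})
reco = MockRecognizer(conf, seed=11)
rng = np.random.default_rng(11)

S = I = D = N = 0
for _ in range(500):
    truth = list(rng.choice(list(chart.vocab), size=5, replace=False))
    hyp = reco.transcribe(" ".join(truth)).text.split()
    r = wer(truth, hyp)
    S, I, D, N = S + r.S, I + r.I, D + r.D, N + r.N

print(f"pooled over {N} reference tokens: S={S} I={I} D={D}")
print(f"WER = {100.0 * (S + I + D) / N:.2f}%  (expected near the 10% substitution rate)")
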