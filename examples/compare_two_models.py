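"""Head-to-head comparison of two non-nested regression models.

Builds a small synthetic dataset in which the response depends on x2 and
(weakly) on x3, then asks: is the model using x2 closer to the truth than
the model using x3?  Classical tests cannot compare these two candidates —
neither is nested in the other — but the bootstrap discrepancy comparison
probability (BDCP) can.
"""

import numpy as np
import pandas as pd

from bdcp import DataSet, ModelSpec, compare

rng = np.random.default_rng(42)
n = 60
x2 = rng.normal(0, 3, n)
x3 = rng.normal(0, 3, n)
y = 1.0 + 1.2 * x2 + 0.2 * x3 + rng.normal(0, 2, n)
frame = pd.DataFrame({"y": y, "x2": x2, "x3": x3})

data = DataSet.from_frame(frame, response="y")
null_model = ModelSpec(("x2",))   # the candidate we call "null"
alt_model = ModelSpec(("x3",))    # the competing candidate

result = compare(data, null_model, alt_model, J=500, seed=7)

print(f"n = {data.n}, J = {result.J} paired bootstrap resamples")
print(f"BDCP  (uncorrected)     = {result.bdcp:.3f}")
print(f"BDCPk (k-corrected)     = {result.bdcp_k:.3f}")
print(f"BDCPb (bootstrap corr.) = {result.bdcp_b:.3f}")
print(f"null (x2):  BD = {result.bd1:.1f}, BDk = {result.bd1_k:.1f}, BDb = {result.bd1_b:.1f}")
print(f"alt  (x3):  BD = {result.bd2:.1f}, BDk = {result.bd2_k:.1f}, BDb = {result.bd2_b:.1f}")
print()
print("Each probability estimates Pr[the x2 model is closer to the truth in")
print("Kullback-Leibler discrepancy than the x3 model]; values near 1 favour")
print("the x2 model.  Both candidates have the same size, so the k correction")
print("cannot change the verdict (BDCPk = BDCP); the discrepancy point")
print("estimates (smaller = better) tell the same story.")
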