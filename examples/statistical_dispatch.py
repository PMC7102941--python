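"""Gate-and-dispatch statistics plus robust outlier removal.

Shows the decision tree on three kinds of data (Gaussian pairs, skewed
groups, a multi-group design with one shifted group) and the ROUT-style
outlier flagging at Q = 1%.
"""

import numpy as np

from trnafret.stats import dispatch_comparison, gate, rout_outliers

rng = np.random.default_rng(4)

# two Gaussian groups -> Student's t
a, b = rng.normal(0, 1, 40), rng.normal(0.3, 1, 40)
res = dispatch_comparison([a, b])
print(f"Gaussian pair     -> {res.test_name:20s} p={res.p_value:.3f}")

# skewed data -> Mann-Whitney
res = dispatch_comparison([rng.exponential(1, 80), rng.exponential(1.6, 80)])
print(f"skewed pair       -> {res.test_name:20s} p={res.p_value:.3f}")

# three groups, one shifted -> ANOVA + Tukey
gs = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(1.2, 1, 30)]
res = dispatch_comparison(gs, names=["ctrl", "g1", "g2"])
print(f"three groups      -> {res.test_name:20s} omnibus p={res.p_value:.4f}")
print(res.posthoc[["group1", "group2", "p_adjusted"]].to_string(index=False))

# ROUT outlier flagging
x = np.r_[rng.normal(10, 2, 30), 60.0]
rep = rout_outliers(x, q=0.01)
print(f"ROUT: flagged {rep.n_outliers} of {x.size} values "
      f"(center={rep.center:.2f}, robust SD={rep.scale:.2f}); "
      f"the planted value 60.0 is flagged: {bool(rep.outlier[-1])}")
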