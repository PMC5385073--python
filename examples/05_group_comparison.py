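"""Per-feature Wilcoxon rank-sum comparison with multiple-testing correction,
signed percentage effect sizes, and a reporter z-score for a KO module.
"""

import numpy as np
import pandas as pd

import metagut as mg
from metagut.stats import comparison_frame

rng = np.random.default_rng(31)
kos = [f"K{i:05d}" for i in range(60)]
base = rng.lognormal(sigma=1.0, size=60)
rows, labels = [], {}
for i in range(16):
    group = "A" if i < 8 else "B"
    expected = base.copy()
    if group == "A":
        expected[:6] *= 3.0  # the first six KOs are enriched in group A
    rows.append(expected * rng.lognormal(sigma=0.4, size=60))
    labels[f"s{i:02d}"] = group
data = pd.DataFrame(rows, index=list(labels), columns=kos)
profile = mg.AbundanceProfile(data.div(data.sum(axis=1), axis=0), level="KO")

results = mg.wilcoxon_compare(profile, labels, correction="hommel", alpha=0.05)
frame = comparison_frame(results)
significant = frame[frame.p_adjusted < 0.05]
print(f"features tested:      {len(frame)}")
print(f"significant (Hommel): {len(significant)}")
print(significant.head(6).round(4).to_string(index=False))

module = mg.FunctionalModule("planted", frozenset(kos[:6]), reaction_count=6)
z_adj, z_raw = mg.reporter_zscore(results, module.kos, n_background=2000, seed=31)
print(f"reporter score:       raw Z = {z_raw:.2f}, background-corrected Z = {z_adj:.2f}")

# The six planted KOs come out significant with positive effect sizes
# (higher in group A), and the module containing them scores far above the
# random-KO background.
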