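"""Fisher-z significance machinery: thresholds, sample size, minimum difference.

Prints the correlation value that reaches significance at several alpha
levels for 27 samples, the minimum sample size needed to keep the
standard error of a strong correlation at or below 0.1, and the minimum
correlation difference that counts as a significant change between two
groups of 27 samples.
"""

from scipy.stats import norm

from metcorrnet import correlation_threshold, differential_threshold, min_samples

print("Correlation significance thresholds at N = 27:")
for alpha in (1e-6, 1e-4, 1e-3, 0.01, 0.05):
    z_t = float(norm.ppf(1 - alpha / 2))
    print(f"  alpha = {alpha:<6g} -> |r| > {correlation_threshold(z_t, 27):.6f}")

n = min_samples(0.7, 0.1, decimals=4)
print(f"\nMinimum samples for SE(r=0.7) <= 0.1 (4-decimal rounding): {n}")
print(f"  (strict inequality: {min_samples(0.7, 0.1, decimals=None)})")

d = differential_threshold(0.7, 27, 27, 1.959964)
print(f"\nMinimum significant difference vs r = 0.7, 27 vs 27 samples: {d:.3f}")
print("=> decision rule: one |r| > 0.7 AND |r_A - r_B| > 0.407")
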