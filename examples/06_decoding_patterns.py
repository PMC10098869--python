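"""Turn decoder weights into interpretable forward-model patterns.

Decoder weights are not directly interpretable; the forward-model transform
A = (1/g) Sigma_Y W Sigma_Z^(-1/2) recovers where the decoded information
actually lives.  On a noiseless linear simulation the transformed pattern is
collinear with the true forward mixing, which raw weights are not.
"""

import numpy as np

from trajdec import patterns, rewpls

rng = np.random.default_rng(6)
n, d, m = 4000, 24, 6

z = rng.standard_normal((m, n))                  # independent latent kinematics
a_true = rng.standard_normal((d, m))             # true forward mixing
y = a_true @ z + 0.05 * rng.standard_normal((d, n))

state = rewpls.CovarianceState.initial(d, m)
rewpls.update_covariances(state, y, z)
model = rewpls.fit_from_covariances(state, m)

sigma_y = np.cov(y, bias=True)
sigma_z = np.cov(z, bias=True)
pat = patterns.decoding_pattern(model, sigma_y, sigma_z, gfp=1.0)


def cosine(u, v):
    return abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))


print("per-kinematic |cosine| with the true forward-mixing column:")
print("  column     raw weights   transformed pattern")
for k in range(m):
    c_w = cosine(model.coef[:, k], a_true[:, k])
    c_a = cosine(pat.pattern[:, k], a_true[:, k])
    print(f"  {k}          {c_w:.3f}         {c_a:.3f}")

# embed a small collection of patterns (two model families) in 2-D
group_a = [pat.pattern[:, 0] + 0.02 * rng.standard_normal(d) for _ in range(6)]
group_b = [-pat.pattern[:, 1] + 0.02 * rng.standard_normal(d) for _ in range(6)]
coords = patterns.embed_patterns(np.vstack(group_a + group_b), perplexity=4, seed=0)
spread_a = coords[:6].mean(axis=0)
spread_b = coords[6:].mean(axis=0)
print(f"t-SNE embedding: group centroids {np.round(spread_a, 1)} vs "
      f"{np.round(spread_b, 1)} (distinct model families separate)")
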