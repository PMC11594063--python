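"""The resampling comparison on controlled potential-value samples.

Three scenarios on synthetic distributions: a null pair (same law), a
location shift at the scale the method is built to resolve, and an
equal-mean shape change that only the tail-sensitive AD test can see.
"""

import surfdelta as sd

cfg = sd.ResamplingConfig(n_points=100, n_iterations=1000, seed=1)

print("scenario                 p_T       p_KS      p_AD      median shift")
for label, kwargs in [
    ("null (same law)", dict(shift=0.0)),
    ("location shift +0.41", dict(shift=0.41)),
    ("equal-mean shape change", dict(shift=0.0, shape="bimodal", mode_scale=1.5)),
]:
    x, y = sd.sample_potential_pair(5000, seed=11, **kwargs)
    r = sd.resampled_comparison(x, y, cfg)
    print(f"{label:<24} {sd.format_p(r.p_t):>9} {sd.format_p(r.p_ks):>9} "
          f"{sd.format_p(r.p_ad):>9} {r.median_shift:+13.3f}")
# Expected pattern: the null row is non-significant everywhere; the shift
# row is significant for all three tests; the shape-change row is invisible
# to the mean-based t test but decisive for AD (and KS to a lesser degree),
# which is why AD is the headline statistic for surface-potential
# distributions. (The shape-change row's median shift is an artifact: the
# empirical median of a symmetric bimodal sample jumps between the modes.)
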