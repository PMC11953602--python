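"""Finite-population sample-size calculation for a prevalence estimate.

n0 = z^2 p (1-p) / e^2 corrected as n = n0 / (1 + (n0-1)/N).  With a
target population of 150,000 children, an expected 7% prevalence, 95%
confidence and a 5% margin, about 100 participants are required.
"""

from milescreen import SampleSizeSpec, sample_size

spec = SampleSizeSpec(population=150_000, prevalence=0.07,
                      z=1.96, margin=0.05)
print(f"required sample size: {sample_size(spec)}")

infinite = SampleSizeSpec(population=None, prevalence=0.07,
                          z=1.96, margin=0.05)
print(f"without the finite-population correction: {sample_size(infinite)}")

tight = SampleSizeSpec(population=150_000, prevalence=0.07,
                       z=1.96, margin=0.01)
print(f"at a 1% margin of error: {sample_size(tight)}")
# The correction only matters when n0 approaches N; tightening the margin
# from 5% to 1% scales the uncorrected requirement ~25-fold.
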