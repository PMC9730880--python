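"""Growth-rate arithmetic for a single lesion, step by step.

A lesion measured 19 -> 20 -> 26 mm at -90/0/+90 days grows slowly before
treatment and much faster after it: the post-treatment growth rate is more
than five times the reference rate, so with RECIST progression it counts as
hyperprogressive.
"""

from hyperrad.hyperprogression import LesionMeasurements, classify_hpl, growth_rate

tg_ref = growth_rate(19, 20, -90, 0)
tg_exp = growth_rate(20, 26, 0, 90)
print(f"reference growth rate  (pre->base): {tg_ref:.6f} /day")
print(f"experimental growth rate (base->fu): {tg_exp:.6f} /day")
print(f"ratio: {tg_exp / tg_ref:.2f}  (>= 2 means doubling)")

m = LesionMeasurements("L1", "P1", 19, 20, 26, -90, 0, 90)
a = classify_hpl(m)
print(f"RECIST progression: {a.recist_pd}, hyperprogressive lesion: {a.hpl}")
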