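"""Fit a saturating dose-response curve to epinephrine percent changes.

Evaluates the packaged pharmacodynamic model at the five-point epinephrine
design (0, 0.1, 0.5, 5, 50 µM), expresses each response as percent change
from baseline, and fits the Hill model R(c) = Rmax c^n / (c^n + EC50^n).
The fitted plateau (Rmax) should match the model's saturating increase
(~40%), reached by 5 µM.
"""

import numpy as np

from organchip.pharm import DoseResponse, fit_dose_response, percent_change
from organchip.pkpd import beat_rate_response, default_pd_params

pd_params = default_pd_params()
baseline = beat_rate_response(0.0, 0.0, pd_params)
doses = np.array([0.0, 0.1, 0.5, 5.0, 50.0])
responses = [percent_change(baseline, beat_rate_response(d, 0.0, pd_params))
             for d in doses]

for d, r in zip(doses, responses):
    print(f"  epinephrine {d:5.1f} uM -> {r:+6.2f}% beat-rate change")

fit = fit_dose_response(DoseResponse(doses, responses))
print(f"\nHill fit: Rmax = {fit.Rmax_pct:.1f}%  EC50 = {fit.EC50_uM:.3f} uM  "
      f"n = {fit.hill_n:.2f}  (rss {fit.rss:.2e})")
print("Rmax is the plateau percent increase; EC50 the half-maximal dose.")
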