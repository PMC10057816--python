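"""Cosinor fit and rhythm detection on a circadian temperature channel.

Generates three days of 2 h-binned subcutaneous temperature with a known
(mesor, amplitude, acrophase) and recovers the parameters; then shows the
zero-amplitude rhythm test on signal vs pure noise.
"""

import numpy as np

from cardiotel import (
    CircadianGenSpec, ExperimentDesign, acrophase_to_hours, fit_cosinor,
    gen_circadian,
)

design = ExperimentDesign()
spec = CircadianGenSpec(mesor=33.81, amplitude=0.78, acrophase=-0.69,
                        noise_sd=0.2, sampling_interval_min=120.0, days=3, seed=5)
fit = fit_cosinor(gen_circadian(spec, design))
print(f"true  (M, A, phi) = (33.81, 0.78, -0.69)")
print(f"fitted (M, A, phi) = ({fit.mesor:.2f}, {fit.amplitude:.2f}, {fit.acrophase:.2f})")
print(f"fitted peak at {acrophase_to_hours(fit.acrophase):.1f} h after midnight "
      f"(early dark cycle), rhythm-test p = {fit.p_rhythm:.2e}")

null = gen_circadian(CircadianGenSpec(mesor=33.81, amplitude=0.0, noise_sd=0.2,
                                      sampling_interval_min=120.0, days=3, seed=7),
                     design)
p_null = fit_cosinor(null).p_rhythm
print(f"pure-noise series: rhythm-test p = {p_null:.2f} (no rhythm detected)")
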