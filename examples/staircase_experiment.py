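"""Simulated 2AFC staircase estimating the limiting spatial frequency.

A template-matching observer (defocus blur + Ricco summation + recognition
criterion) replaces the human participant.  The staircase lowers the
carrier frequency after two correct identifications and raises it after an
error, converging on the lowest frequency at which the hidden figure is
still recognized.  That limiting frequency is then mapped to a predicted
logMAR acuity with the plus-lens regression line.
"""

import math

from pwmillusion import (PLUS_LENS_MODEL, DefocusSpec, StaircaseConfig,
                         ViewingGeometry, apply_blur, defocus_psf,
                         make_silhouette, predict_va, ricco_summation,
                         staircase_run)
from pwmillusion.psychophysics import make_image_observer

# 40 px/deg: a 256-px stimulus spans 6.4 deg, so 1-12 cpd carriers fit
geom = ViewingGeometry(100.0, 2 * 100 * math.tan(math.radians(0.5)) / 40.0)
templates = {s: make_silhouette(s, 256) for s in ("disc", "cross")}

for diopters in (1.0, 2.0):
    psf = defocus_psf(DefocusSpec(defocus_d=diopters), geom)

    def observer(img, p=psf):
        return ricco_summation(apply_blur(img, p), 10.0, geom)

    trial = make_image_observer(templates, geom, observer, criterion=0.4)
    est, log = staircase_run(trial, StaircaseConfig(start_sf_cpd=12.0),
                             template_names=list(templates), seed=42)
    va = predict_va(est.limiting_sf_cpd, PLUS_LENS_MODEL)
    print(f"defocus {diopters:.0f} D: limiting SF = {est.limiting_sf_cpd:.2f} cpd "
          f"({est.n_trials} trials, {est.n_reversals} reversals) "
          f"-> predicted acuity {va:+.2f} logMAR")
# More blur -> lower limiting SF -> worse (higher) predicted logMAR.
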