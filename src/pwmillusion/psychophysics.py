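"""Simulated two-alternative forced-choice staircase experiment.

A simulated observer replaces the human participant: the stimulus is
demodulated through a configurable pipeline of optical and neural stages,
correlated against low-passed silhouette templates, and the best match is
reported if it clears a recognition criterion.  An adaptive transformed
staircase then estimates the *limiting spatial frequency* — the lowest
carrier frequency (in cycles per degree) at which the hidden figure is
still identified — exactly the quantity the live experiment measures.

Acuity prediction maps a limiting spatial frequency to logMAR visual acuity
through per-degradation-type linear models; the published coefficients are
bundled as :data:`OCCLUSION_FOIL_MODEL` and :data:`PLUS_LENS_MODEL`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .halftone import HalftoneImage, HalftoneParams, SourceImage, render
from .optics import ViewingGeometry, f_px_of_cpd

__all__ = [
    "NOT_RECOGNIZED",
    "StaircaseConfig",
    "TrialRecord",
    "ThresholdEstimate",
    "AcuityModel",
    "OCCLUSION_FOIL_MODEL",
    "PLUS_LENS_MODEL",
    "simulated_observer",
    "make_image_observer",
    "staircase_run",
    "method_of_limits_run",
    "predict_va",
    "min_sf_for_va",
]

NOT_RECOGNIZED = "not_recognized"


@dataclass(frozen=True)
class StaircaseConfig:
    """Transformed 1-up/2-down staircase on log2 spatial frequency.

    Two consecutive correct responses lower the spatial frequency (the task
    gets harder as the zigzag becomes resolvable); one incorrect response
    raises it.  The step is halved after each of the first
    ``n_step_halvings`` reversals; the run ends after ``n_reversals``
    reversals and the threshold is the geometric mean of the last
    ``n_estimate_reversals`` reversal frequencies.  This converges to the
    70.7% point of the psychometric function in a 2AFC task.
    """

    start_sf_cpd: float = 8.0
    initial_step_log2: float = 0.5
    n_step_halvings: int = 4
    n_reversals: int = 8
    n_estimate_reversals: int = 6
    sf_bounds_cpd: tuple = (0.5, 16.0)
    n_down: int = 2           # correct responses per downward step
    max_trials: int = 200
    timeout_s: float = 10.0   # schedule metadata; the simulated observer never misses
    isi_s: float = 1.5

    def __post_init__(self) -> None:
        lo, hi = self.sf_bounds_cpd
        if not (0 < lo < hi):
            raise ValueError("sf_bounds_cpd must be positive and increasing")
        if not (lo <= self.start_sf_cpd <= hi):
            raise ValueError("start_sf_cpd must lie within sf_bounds_cpd")
        if self.n_reversals < 4:
            raise ValueError("need at least 4 reversals")
        if not self.initial_step_log2 > 0:
            raise ValueError("initial_step_log2 must be positive")
        if self.n_estimate_reversals > self.n_reversals:
            raise ValueError("n_estimate_reversals cannot exceed n_reversals")

    @property
    def final_step_log2(self) -> float:
        return self.initial_step_log2 / 2 ** self.n_step_halvings


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    sf_cpd: float
    template: str
    response: str
    correct: bool
    missed: bool = False


@dataclass(frozen=True)
class ThresholdEstimate:
    """Limiting spatial frequency with dispersion over reversal values."""

    limiting_sf_cpd: float
    sd_cpd: float
    n_trials: int
    n_reversals: int
    converged: bool = True


@dataclass(frozen=True)
class AcuityModel:
    """Linear map from limiting spatial frequency (cpd) to logMAR acuity."""

    degradation_type: str
    intercept_logmar: float
    slope_logmar_per_cpd: float

    def __post_init__(self) -> None:
        if not self.slope_logmar_per_cpd < 0:
            raise ValueError("slope must be negative: acuity improves "
                             "(logMAR decreases) with higher limiting SF")


#: Published per-degradation-type regression coefficients
#: (logMAR = intercept + slope * limiting SF in cpd).
OCCLUSION_FOIL_MODEL = AcuityModel("occlusion_foil", 1.1519, -0.2365)
PLUS_LENS_MODEL = AcuityModel("plus_lens", 1.4563, -0.2940)


def predict_va(limiting_sf_cpd: float, model: AcuityModel) -> float:
    """Predicted visual acuity (logMAR) at a given limiting spatial
    frequency."""
    if not limiting_sf_cpd >= 0:
        raise ValueError("limiting_sf_cpd must be nonnegative")
    return model.intercept_logmar + model.slope_logmar_per_cpd * limiting_sf_cpd


def min_sf_for_va(va_logmar: float, model: AcuityModel) -> float:
    """Algebraic inverse of :func:`predict_va`: the spatial frequency at
    which the linear model predicts the given acuity.

    Note this is the inversion of the forward acuity-on-frequency line; a
    regression of frequency on acuity fitted to data would give slightly
    different numbers.
    """
    if model.slope_logmar_per_cpd == 0:
        raise ValueError("zero slope cannot be inverted")
    return (model.intercept_logmar - va_logmar) / abs(model.slope_logmar_per_cpd)


def simulated_observer(stimulus: HalftoneImage,
                       templates: Mapping[str, SourceImage],
                       observer: Callable[[np.ndarray], np.ndarray],
                       criterion: float,
                       template_sigma_px: float = 3.0) -> str:
    """One forced-choice response of a template-matching observer.

    The stimulus is demodulated by ``observer`` (any composition of optical
    and neural stages mapping image -> image); the result is Pearson-
    correlated against each lightly smoothed, polarity-matched template
    (figure regions are darker in the demodulated image, so templates are
    negated).  The best-matching template id is returned if its correlation
    exceeds ``criterion``, else :data:`NOT_RECOGNIZED`.
    """
    if len(templates) < 2:
        raise ValueError("forced choice needs at least two templates")
    if not (0 < criterion < 1):
        if criterion >= 1:
            return NOT_RECOGNIZED  # unattainable criterion
        raise ValueError("criterion must be in (0, 1)")
    demod = observer(stimulus.values)
    demod = demod - demod.mean()
    dnorm = float(np.sqrt(np.sum(demod ** 2)))
    if dnorm == 0:
        return NOT_RECOGNIZED
    best_name, best_r = NOT_RECOGNIZED, -np.inf
    for name, tpl in templates.items():
        t = ndimage.gaussian_filter(1.0 - tpl.values, template_sigma_px)
        t = t - t.mean()
        tnorm = float(np.sqrt(np.sum(t ** 2)))
        if tnorm == 0:
            continue
        r = float(np.sum(demod * t)) / (dnorm * tnorm)
        if r > best_r:
            best_name, best_r = name, r
    return best_name if best_r > criterion else NOT_RECOGNIZED


def _render_observer_trial(template_name: str,
                           templates: Mapping[str, SourceImage],
                           sf_cpd: float,
                           geom: ViewingGeometry,
                           params: HalftoneParams,
                           observer: Callable[[np.ndarray], np.ndarray],
                           criterion: float) -> str:
    from dataclasses import replace
    f_px = f_px_of_cpd(sf_cpd, geom)
    stim = render(templates[template_name], replace(params, f=f_px))
    return simulated_observer(stim, templates, observer, criterion)


def make_image_observer(templates: Mapping[str, SourceImage],
                        geom: ViewingGeometry,
                        observer: Callable[[np.ndarray], np.ndarray],
                        criterion: float = 0.5,
                        params: HalftoneParams | None = None,
                        ) -> Callable[[float, str], bool]:
    """Wrap a demodulation pipeline into a trial function
    ``(sf_cpd, template_name) -> correct`` for :func:`staircase_run`."""
    from .halftone import FIG_PARAMS
    p = params if params is not None else FIG_PARAMS
    def trial(sf_cpd: float, template_name: str) -> bool:
        resp = _render_observer_trial(template_name, templates, sf_cpd,
                                      geom, p, observer, criterion)
        return resp == template_name
    return trial


def staircase_run(trial_fn: Callable[[float, str], bool],
                  config: StaircaseConfig,
                  template_names: Sequence[str] = ("a", "b"),
                  seed: int | np.random.Generator = 0,
                  ) -> tuple[ThresholdEstimate, list[TrialRecord]]:
    """Run the adaptive staircase against a trial function.

    ``trial_fn(sf_cpd, template_name) -> bool`` reports whether the observer
    identified the randomly chosen silhouette at that carrier frequency.
    Identical seeds give identical trial logs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = (math.log2(b) for b in config.sf_bounds_cpd)
    x = math.log2(config.start_sf_cpd)
    step = config.initial_step_log2
    reversals: list[float] = []
    records: list[TrialRecord] = []
    streak = 0
    last_direction = 0  # +1 = SF raised, -1 = SF lowered
    names = list(template_names)
    while len(reversals) < config.n_reversals and len(records) < config.max_trials:
        name = names[rng.integers(len(names))]
        sf = float(2.0 ** x)
        correct = bool(trial_fn(sf, name))
        records.append(TrialRecord(
            trial=len(records), sf_cpd=sf, template=name,
            response=name if correct else NOT_RECOGNIZED, correct=correct))
        if correct:
            streak += 1
            direction = -1 if streak >= config.n_down else 0
        else:
            streak = 0
            direction = +1
        if direction:
            if streak >= config.n_down:
                streak = 0
            if last_direction and direction != last_direction:
                reversals.append(sf)
                if len(reversals) <= config.n_step_halvings:
                    step /= 2.0
            last_direction = direction
            x = min(max(x + direction * step, lo), hi)
    converged = len(reversals) >= config.n_reversals
    used = reversals[-config.n_estimate_reversals:] if reversals else [float(2.0 ** x)]
    log_used = np.log2(used)
    estimate = float(2.0 ** np.mean(log_used))
    estimate = min(max(estimate, config.sf_bounds_cpd[0]), config.sf_bounds_cpd[1])
    return (ThresholdEstimate(
        limiting_sf_cpd=estimate,
        sd_cpd=float(np.std(used, ddof=1)) if len(used) > 1 else 0.0,
        n_trials=len(records),
        n_reversals=len(reversals),
        converged=converged), records)


def method_of_limits_run(trial_fn: Callable[[float, str], bool],
                         start_sf_cpd: float = 8.0,
                         step_log2: float = 0.125,
                         sf_floor_cpd: float = 0.5,
                         n_misses_to_stop: int = 2,
                         template_names: Sequence[str] = ("a", "b"),
                         seed: int | np.random.Generator = 0,
                         ) -> tuple[ThresholdEstimate, list[TrialRecord]]:
    """Descending method of limits: lower the carrier frequency in fixed
    log steps until the figure stops being recognized.

    The limiting spatial frequency is the last frequency identified
    correctly before ``n_misses_to_stop`` consecutive failures.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(template_names)
    x = math.log2(start_sf_cpd)
    floor = math.log2(sf_floor_cpd)
    records: list[TrialRecord] = []
    last_correct_sf = None
    misses = 0
    while x >= floor:
        name = names[rng.integers(len(names))]
        sf = float(2.0 ** x)
        correct = bool(trial_fn(sf, name))
        records.append(TrialRecord(
            trial=len(records), sf_cpd=sf, template=name,
            response=name if correct else NOT_RECOGNIZED, correct=correct))
        if correct:
            last_correct_sf = sf
            misses = 0
        else:
            misses += 1
            if misses >= n_misses_to_stop:
                break
        x -= step_log2
    est = last_correct_sf if last_correct_sf is not None else sf_floor_cpd
    return (ThresholdEstimate(
        limiting_sf_cpd=float(est), sd_cpd=0.0, n_trials=len(records),
        n_reversals=0, converged=last_correct_sf is not None), records)
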