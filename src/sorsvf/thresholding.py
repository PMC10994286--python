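"""Single-location threshold procedures and the simulated responder.

The simulated patient answers seen/not-seen according to a piecewise-linear
frequency-of-seeing curve: the probability of seeing a stimulus of
intensity ``s`` dB (higher dB = dimmer) ramps linearly from ``1 - fn`` at
``t - w`` down to the false-positive floor ``fp`` at ``t + w``, where ``t``
is the true threshold and ``w`` the ramp half-width.  This is the standard
piecewise-linear approximation of a cumulative-Gaussian psychometric
function; ``w = 2`` dB corresponds roughly to a 1.6 dB frequency-of-seeing
slope.  An optional threshold-dependent (Henson-type) half-width makes the
curve shallower at damaged locations.

Two estimation procedures are provided:

* ZEST — Bayesian: a probability mass function over candidate thresholds
  (0..40 dB, 1 dB steps) is updated after every presentation; stimuli are
  placed at the posterior mean; the procedure stops when the posterior
  standard deviation falls below 2.0 dB and reports the posterior mean.
* 4-2 staircase — stimuli step 4 dB (dimmer after seen, brighter after
  not-seen) until the first response reversal, then 2 dB until the second;
  the last seen level is the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fields import DB_MIN, DB_MAX, FieldDataset

DOMAIN = np.arange(int(DB_MIN), int(DB_MAX) + 1, dtype=float)  # 0..40 dB


# ---------------------------------------------------------------------------
# Responder model

@dataclass(frozen=True)
class PsychometricModel:
    """Frequency-of-seeing curve of a simulated responder."""

    true_threshold: float
    fp: float = 0.03
    fn: float = 0.03
    ramp_halfwidth: float = 2.0

    def __post_init__(self):
        if not (0 <= self.fp <= 1 and 0 <= self.fn <= 1 and self.fp + self.fn < 1 + 1e-12):
            raise ValueError("need 0 <= fp, fn and fp + fn < 1")
        if self.ramp_halfwidth < 0:
            raise ValueError("ramp_halfwidth must be >= 0")


def henson_halfwidth(threshold: float, cap: float = 6.0) -> float:
    """Threshold-dependent ramp half-width: shallower curves at damaged points.

    Follows the empirical log-linear growth of frequency-of-seeing spread
    with sensitivity loss (Henson-type), capped at ``cap`` dB.
    """
    return float(min(cap, math.exp(-0.081 * threshold + 1.5)))


def p_seen(model: PsychometricModel, stimulus: float) -> float:
    """Probability the responder reports 'seen' for a stimulus in dB."""
    t, w = model.true_threshold, model.ramp_halfwidth
    if w == 0:
        base = 0.5 if stimulus == t else (1.0 if stimulus < t else 0.0)
    else:
        base = min(1.0, max(0.0, 0.5 + (t - stimulus) / (2 * w)))
    return model.fp + (1 - model.fp - model.fn) * base


def simulate_response(model: PsychometricModel, stimulus: float, rng: np.random.Generator) -> bool:
    """One Bernoulli seen/not-seen draw; reproducible under a seeded rng."""
    return bool(rng.random() < p_seen(model, stimulus))


# ---------------------------------------------------------------------------
# ZEST

@dataclass(frozen=True)
class ZESTConfig:
    """Estimator-side configuration of the ZEST procedure.

    The likelihood assumes fixed ``fp``/``fn`` rates and ramp width for
    the *estimator*, independent of the simulated responder's actual
    reliability (the mismatch is deliberate: a real perimeter does not
    know its patient's error rates).
    """

    prior: np.ndarray = field(default_factory=lambda: np.full(len(DOMAIN), 1 / len(DOMAIN)))
    domain: np.ndarray = field(default_factory=lambda: DOMAIN.copy())
    terminate_sd: float = 2.0
    fp: float = 0.03
    fn: float = 0.03
    ramp_halfwidth: float = 2.0
    max_presentations: int = 30

    def __post_init__(self):
        if abs(float(np.sum(self.prior)) - 1.0) > 1e-12:
            raise ValueError("prior must sum to 1")
        if self.terminate_sd <= 0:
            raise ValueError("terminate_sd must be positive")


@dataclass(frozen=True)
class ZESTState:
    """Posterior PMF over candidate thresholds plus the trial history."""

    pmf: np.ndarray
    history: tuple[tuple[float, bool], ...] = ()


def pmf_mean(domain: np.ndarray, pmf: np.ndarray) -> float:
    return float(np.dot(domain, pmf))


def pmf_sd(domain: np.ndarray, pmf: np.ndarray) -> float:
    m = pmf_mean(domain, pmf)
    return float(np.sqrt(max(0.0, np.dot((domain - m) ** 2, pmf))))


def build_prior(training: FieldDataset | np.ndarray, smoothing: float = 1e-3) -> np.ndarray:
    """Empirical prior PMF: pooled histogram of all training thresholds.

    Values are binned to the nearest 1-dB domain level and the histogram
    normalized; ``smoothing`` is then added to every bin and the PMF
    renormalized.  The additive floor keeps every candidate threshold
    plausible a priori (the histogram of a real training set can be empty
    near the ends of the range, which would make those thresholds
    unreachable however the patient responds).
    """
    M = training.X if isinstance(training, FieldDataset) else np.asarray(training, dtype=float)
    binned = np.clip(np.rint(M.ravel()), DOMAIN[0], DOMAIN[-1]).astype(int)
    counts = np.bincount(binned - int(DOMAIN[0]), minlength=len(DOMAIN)).astype(float)
    pmf = counts / counts.sum() + smoothing
    return pmf / pmf.sum()


def seed_prior(prior: np.ndarray, target_mean: float, domain: np.ndarray = DOMAIN) -> np.ndarray:
    """Translate a prior PMF so its mean lands near ``target_mean``.

    The shift is the nearest integer number of 1-dB bins; mass pushed past
    either end of the domain piles up in the edge bin, then the PMF is
    renormalized.  Used to initialize a location's ZEST from a
    reconstruction-based prediction.
    """
    shift = int(np.rint(target_mean - pmf_mean(domain, prior)))
    if shift == 0:
        return prior.copy()
    out = np.zeros_like(prior)
    n = len(prior)
    for i, p in enumerate(prior):
        j = min(n - 1, max(0, i + shift))
        out[j] += p
    return out / out.sum()


def zest_start(config: ZESTConfig) -> ZESTState:
    return ZESTState(pmf=config.prior / config.prior.sum())


def zest_step(state: ZESTState, config: ZESTConfig, stimulus: float, seen: bool) -> ZESTState:
    """Bayes update of the PMF after one presentation."""
    like = np.array(
        [
            p_seen(
                PsychometricModel(
                    true_threshold=t,
                    fp=config.fp,
                    fn=config.fn,
                    ramp_halfwidth=config.ramp_halfwidth,
                ),
                stimulus,
            )
            for t in config.domain
        ]
    )
    post = state.pmf * (like if seen else 1.0 - like)
    total = post.sum()
    if total <= 0:
        raise ValueError("posterior vanished; use fp, fn > 0 in the likelihood")
    return ZESTState(pmf=post / total, history=state.history + ((stimulus, seen),))


def zest_next_stimulus(state: ZESTState, config: ZESTConfig) -> float:
    """Stimulus placement: posterior mean rounded to the 1-dB grid."""
    return float(np.clip(np.rint(pmf_mean(config.domain, state.pmf)), DB_MIN, DB_MAX))


def zest_done(state: ZESTState, config: ZESTConfig) -> bool:
    return (
        pmf_sd(config.domain, state.pmf) < config.terminate_sd
        or len(state.history) >= config.max_presentations
    )


def zest_estimate(state: ZESTState, config: ZESTConfig) -> float:
    """Final estimate: the (unrounded) posterior mean."""
    return pmf_mean(config.domain, state.pmf)


def run_zest(
    config: ZESTConfig, responder: PsychometricModel, rng: np.random.Generator
) -> tuple[float, int]:
    """Full ZEST loop at one location: (estimate dB, presentation count)."""
    state = zest_start(config)
    while not zest_done(state, config):
        s = zest_next_stimulus(state, config)
        seen = simulate_response(responder, s, rng)
        state = zest_step(state, config, s, seen)
    return zest_estimate(state, config), len(state.history)


def run_zest_trace(
    config: ZESTConfig, responder: PsychometricModel, rng: np.random.Generator
):
    """Like :func:`run_zest` but also return a per-trial log.

    The log is a list of dicts (one per presentation) with the stimulus,
    the response, and the posterior SD after the update — ready for
    ``pandas.DataFrame(log).to_csv(...)``.
    """
    state = zest_start(config)
    log = []
    while not zest_done(state, config):
        s = zest_next_stimulus(state, config)
        seen = simulate_response(responder, s, rng)
        state = zest_step(state, config, s, seen)
        log.append(
            {
                "stimulus_db": s,
                "seen": seen,
                "posterior_sd": pmf_sd(config.domain, state.pmf),
            }
        )
    return zest_estimate(state, config), log


# ---------------------------------------------------------------------------
# 4-2 staircase

def run_staircase(
    start: float,
    responder: PsychometricModel,
    rng: np.random.Generator,
    steps: tuple[float, float] = (4.0, 2.0),
) -> tuple[float, int]:
    """Classic full-threshold staircase: (estimate dB, presentation count).

    Steps of ``steps[0]`` dB until the first response reversal, then
    ``steps[1]`` dB until the second.  Seen moves the stimulus dimmer
    (higher dB), not-seen brighter.  At the 0/40 dB range limits, a second
    consecutive response pinned at the same extreme counts as a reversal.
    The estimate is the level of the last seen stimulus (0 dB if nothing
    was ever seen).
    """
    level = float(np.clip(start, DB_MIN, DB_MAX))
    step = steps[0]
    direction = 0  # +1 after seen (dimmer), -1 after not-seen
    reversals = 0
    last_seen: float | None = None
    pinned = 0
    n = 0
    while reversals < 2 and n < 50:
        seen = simulate_response(responder, level, rng)
        n += 1
        if seen:
            last_seen = level
        new_dir = 1 if seen else -1
        if direction != 0 and new_dir != direction:
            reversals += 1
            if reversals == 1:
                step = steps[1]
            if reversals >= 2:
                break
        direction = new_dir
        nxt = float(np.clip(level + new_dir * step, DB_MIN, DB_MAX))
        if nxt == level:  # pinned at a range limit
            pinned += 1
            if pinned >= 1:  # next same-extreme response => reversal
                reversals += 1
                if reversals == 1:
                    step = steps[1]
                pinned = 0
        else:
            pinned = 0
        level = nxt
    return (last_seen if last_seen is not None else DB_MIN), n
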