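"""Synthetic glaucomatous visual-field generator.

Real glaucomatous fields are strongly structured: thresholds at
neighbouring locations within a hemifield are highly correlated, loss
follows a handful of archetypical patterns (arcuate defects arcing around
fixation, nasal steps that respect the horizontal midline, temporal
wedges, diffuse depression), and the whole dataset is well described by a
low-dimensional linear embedding.  The generator reproduces exactly this
structure so the reconstruction and testing pipeline can be trained and
evaluated without any external dataset: each simulated eye superposes a
normal hill of vision, an eye-level height offset, a severity-scaled
mixture of defect archetypes, and per-visit Gaussian measurement noise.

What it does *not* emulate: progression over visits (visits share the
eye-level defect), floor-effect censoring beyond simple clipping at
0 dB, and the particular prevalence mix of any real clinic population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import DB_MIN, DB_MAX, FieldDataset
from .grid import GridSpec, build_24_2_grid
from .metrics import severity_class

SEVERITIES = ("normal", "mild", "moderate", "severe")

#: target mean-depression range (dB, positive = loss) drawn per severity class
DEPRESSION_RANGES = {
    "normal": (0.0, 1.0),
    "mild": (1.0, 6.0),
    "moderate": (6.0, 12.0),
    "severe": (12.0, 22.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    ``severity_mix`` gives the prevalence of each class; the label stored
    with a field is re-derived from its realized mean deviation so labels
    always agree with the MD-based stratifier.  ``noise_sd`` is the
    per-location, per-visit measurement noise (test-retest variability);
    ``offset_sd`` the between-eye spread of overall hill height.
    """

    n_eyes: int = 278
    visits_per_eye: int = 5
    severity_mix: dict = field(
        default_factory=lambda: {"normal": 0.35, "mild": 0.30, "moderate": 0.20, "severe": 0.15}
    )
    noise_sd: float = 1.5
    offset_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.severity_mix.values()) - 1.0) > 1e-9:
            raise ValueError("severity_mix must sum to 1")
        if self.noise_sd < 0 or self.n_eyes < 1 or self.visits_per_eye < 1:
            raise ValueError("invalid generator configuration")


def hill_value(x: float, y: float) -> float:
    """Normal hill of vision at (x, y) degrees: ~32 dB centrally, declining
    with eccentricity, with a small constant superior-inferior asymmetry
    (superior field slightly less sensitive)."""
    r2 = x * x + y * y
    v = 33.0 - 0.07 * r2**0.8
    if y > 0:
        v -= 1.0
    return v


def hill_of_vision(grid: GridSpec) -> np.ndarray:
    """Hill-of-vision vector on the grid; blind-spot locations forced low."""
    h = np.array([hill_value(x, y) for x, y in grid.locations])
    for i in grid.blind_spot:
        h[i] = 3.0
    return h


def make_archetypes(grid: GridSpec) -> dict[str, np.ndarray]:
    """Non-negative unit-maximum defect patterns on the grid.

    One global depression plus five focal archetypes confined to their
    named region; focal patterns respect the horizontal midline (the
    hallmark asymmetry of glaucomatous loss).
    """
    xy = grid.coordinates()
    x, y = xy[:, 0], xy[:, 1]
    r = np.hypot(x, y)

    def unit(p: np.ndarray) -> np.ndarray:
        p = np.where(p > 1e-9, p, 0.0)
        return p / p.max()

    patterns = {
        "global": np.ones(grid.n_locations),
        # arcuate: band arcing around fixation at ~15 deg, one hemifield
        "superior_arcuate": unit(np.where(y > 0, np.exp(-(((r - 15) / 6) ** 2)), 0.0)),
        "inferior_arcuate": unit(np.where(y < 0, np.exp(-(((r - 15) / 6) ** 2)), 0.0)),
        # nasal step: deepens toward the nasal periphery, one hemifield
        "superior_nasal_step": unit(np.where(y > 0, np.clip((-x - 3) / 24.0, 0, None), 0.0)),
        "inferior_nasal_step": unit(np.where(y < 0, np.clip((-x - 3) / 24.0, 0, None), 0.0)),
        # temporal wedge: straddles the midline, temporal periphery
        "temporal_wedge": unit(
            np.clip((x - 9) / 12.0, 0, None) * np.exp(-((y / 12.0) ** 2))
        ),
    }
    return patterns


def generate(config: GeneratorConfig, grid: GridSpec | None = None) -> FieldDataset:
    """Draw a synthetic dataset; bit-reproducible under ``config.seed``.

    Eye-level draws (severity, archetype weights, offset) and visit-level
    noise use disjoint seed streams so changing the number of visits never
    perturbs the eye-level parameters.
    """
    grid = grid or build_24_2_grid()
    hill = hill_of_vision(grid)
    patterns = make_archetypes(grid)
    focal = [k for k in patterns if k != "global"]
    nonblind = np.array([i not in grid.blind_spot for i in range(grid.n_locations)])

    rng_eye = np.random.default_rng([int(config.seed) % 2**31, 11])
    rng_visit = np.random.default_rng([int(config.seed) % 2**31, 29])

    classes = list(config.severity_mix)
    probs = np.array([config.severity_mix[c] for c in classes])

    cols, ids, mds = [], [], []
    for e in range(config.n_eyes):
        eye_id = f"eye{e:04d}"
        sev = classes[rng_eye.choice(len(classes), p=probs)]
        lo, hi = DEPRESSION_RANGES[sev]
        depth = rng_eye.uniform(lo, hi)
        offset = rng_eye.normal(0.0, config.offset_sd)
        # mixture of one dominant focal pattern plus diffuse loss
        w = rng_eye.dirichlet(np.full(len(focal), 0.35))
        global_share = rng_eye.uniform(0.2, 0.6)
        deficit = global_share * patterns["global"]
        for name, wk in zip(focal, w):
            deficit = deficit + (1 - global_share) * wk * patterns[name]
        m = deficit[nonblind].mean()
        deficit = deficit * (depth / m if m > 0 else 0.0)
        base = hill + offset - deficit
        for _ in range(config.visits_per_eye):
            noise = rng_visit.normal(0.0, config.noise_sd, grid.n_locations)
            vals = np.clip(base + noise, DB_MIN, DB_MAX)
            cols.append(vals)
            ids.append(eye_id)
            mds.append(float((vals - hill)[nonblind].mean()))
    return FieldDataset(
        X=np.column_stack(cols), eye_ids=ids, grid=grid, md=np.asarray(mds)
    )


def generate_fields(
    n_fields: int, seed: int, grid: GridSpec | None = None, **kwargs
) -> FieldDataset:
    """One visit per eye: a dataset of ``n_fields`` independent fields."""
    cfg = GeneratorConfig(n_eyes=n_fields, visits_per_eye=1, seed=seed, **kwargs)
    return generate(cfg, grid)


def severity_labels(dataset: FieldDataset) -> list[str]:
    """MD-derived class label per field (requires dataset.md)."""
    if dataset.md is None:
        raise ValueError("dataset has no stored mean deviations")
    return [severity_class(m) for m in dataset.md]
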