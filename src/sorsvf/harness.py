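"""End-to-end Monte Carlo simulation of whole-field tests.

A simulated test opens locations in a strategy-defined order in small
batches (default four), runs a threshold procedure at each opened
location against a simulated responder, refreshes the whole-field
reconstruction after every batch, and stops after a fixed number of
locations; untested locations take the final reconstruction value.

Three meta-strategies are supported:

* ``sors`` — locations in the trained plan order; each location's ZEST
  prior (or staircase start) is seeded from the current reconstruction;
* ``quadrant`` — the four quadrant centers first, then breadth-first
  growth outward, each new location seeded with the mean deviation from
  normal of its already-determined within-quadrant neighbours;
* ``independent`` — every location uses the unshifted empirical prior and
  untested locations take the normative hill (no seeding baseline).

Cross-validated evaluation splits by *eye* (never by visit), trains
plans/priors on the training split only, and aggregates point-wise RMSE
and presentation counts at per-batch checkpoints.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import FieldDataset
from .grid import GridSpec
from .metrics import mean_deviation, normative_hill, pointwise_rmse, severity_class
from .sors import SORS, SORSPlan
from .thresholding import (
    PsychometricModel,
    ZESTConfig,
    build_prior,
    run_staircase,
    run_zest,
    seed_prior,
)


@dataclass(frozen=True)
class StrategyConfig:
    """One simulated testing strategy (meta-strategy + procedure + responder)."""

    meta: str = "sors"  # sors | quadrant | independent
    reconstructor: str = "ttpcr"
    n_components: int = 8
    stop_after: int = 54
    batch_size: int = 4
    thresholding: str = "zest"  # zest | staircase
    responder_fp: float = 0.03
    responder_fn: float = 0.03
    ramp_halfwidth: float = 2.0
    terminate_sd: float = 2.0

    def __post_init__(self):
        if self.meta not in ("sors", "quadrant", "independent"):
            raise ValueError(f"unknown meta-strategy {self.meta!r}")
        if not 1 <= self.stop_after <= 54 or self.batch_size < 1:
            raise ValueError("need 1 <= stop_after <= 54 and batch_size >= 1")


@dataclass
class TestResult:
    """Outcome of one simulated field test."""

    final_estimate: np.ndarray
    measured: dict[int, float]
    presentations: dict[int, int]
    trajectory: pd.DataFrame  # columns: k, rmse, rmse_raw, trials

    @property
    def total_trials(self) -> int:
        return int(sum(self.presentations.values()))


def quadrant_order(grid: GridSpec) -> list[int]:
    """Quadrant-center-first breadth-first growth order over the grid."""
    centers = sorted(grid.quadrant_centers().values())
    order, seen = list(centers), set(centers)
    queue = deque(centers)
    while queue:
        i = queue.popleft()
        q = grid.quadrant_of(i)
        nbrs = sorted(j for j in grid.neighbors_of(i)
                      if j not in seen and grid.quadrant_of(j) == q)
        for j in nbrs:
            seen.add(j)
            order.append(j)
            queue.append(j)
    # isolated locations (none on the 24-2 grid) would fall back to index order
    for j in range(grid.n_locations):
        if j not in seen:
            order.append(j)
    return order


def quadrant_growth_seed(
    grid: GridSpec, determined: dict[int, float], normative: np.ndarray, location: int
) -> float:
    """Staircase/ZEST start value for a grown location.

    The location inherits the mean deviation from the normative hill of
    its already-determined neighbours in the same quadrant.
    """
    if location in grid.quadrant_centers().values():
        raise ValueError("quadrant centers use the unshifted prior, not a grown seed")
    q = grid.quadrant_of(location)
    devs = [
        determined[j] - normative[j]
        for j in grid.neighbors_of(location)
        if j in determined and grid.quadrant_of(j) == q
    ]
    if not devs:
        raise ValueError(f"location {location} has no determined within-quadrant neighbor")
    return float(normative[location] + np.mean(devs))


def _quadrant_estimate(
    grid: GridSpec, measured: dict[int, float], normative: np.ndarray
) -> np.ndarray:
    """Growth-map estimate: measured where tested, propagated deviation elsewhere."""
    est = normative.copy().astype(float)
    for loc in range(grid.n_locations):
        if loc in measured:
            est[loc] = measured[loc]
            continue
        q = grid.quadrant_of(loc)
        devs = [
            measured[j] - normative[j]
            for j in grid.neighbors_of(loc)
            if j in measured and grid.quadrant_of(j) == q
        ]
        if devs:
            est[loc] = normative[loc] + float(np.mean(devs))
    return est


def run_field_test(
    strategy: StrategyConfig,
    truth: np.ndarray,
    prior: np.ndarray,
    normative: np.ndarray,
    rng: np.random.Generator,
    plan: SORSPlan | None = None,
    grid: GridSpec | None = None,
) -> TestResult:
    """Simulate one complete visual-field test of a true field.

    ``prior`` is the pooled empirical threshold PMF from the training
    split; ``normative`` its hill of vision.  For ``sors`` a fitted plan
    is required and ``grid`` defaults to the plan's.
    """
    if strategy.meta == "sors":
        if plan is None:
            raise ValueError("sors strategy requires a fitted SORSPlan")
        grid = plan.grid
        order = list(plan.order)
    else:
        if grid is None:
            grid = (plan.grid if plan is not None else None) or __default_grid()
        order = quadrant_order(grid) if strategy.meta == "quadrant" else list(range(grid.n_locations))
    truth = np.asarray(truth, dtype=float)
    centers = set(grid.quadrant_centers().values())

    measured: dict[int, float] = {}
    counts: dict[int, int] = {}
    current_est = normative.copy().astype(float)
    rows = []
    k = 0
    while k < strategy.stop_after:
        batch = order[k: min(k + strategy.batch_size, strategy.stop_after)]
        for loc in batch:
            seed_db = None
            if strategy.meta == "sors":
                seed_db = float(current_est[loc])
            elif strategy.meta == "quadrant" and loc not in centers:
                seed_db = quadrant_growth_seed(grid, measured, normative, loc)
            responder = PsychometricModel(
                true_threshold=float(truth[loc]),
                fp=strategy.responder_fp,
                fn=strategy.responder_fn,
                ramp_halfwidth=strategy.ramp_halfwidth,
            )
            if strategy.thresholding == "zest":
                p = prior if seed_db is None else seed_prior(prior, seed_db)
                cfg = ZESTConfig(prior=p, terminate_sd=strategy.terminate_sd)
                est, n = run_zest(cfg, responder, rng)
            else:
                start = float(np.rint(seed_db if seed_db is not None else normative[loc]))
                est, n = run_staircase(start, responder, rng)
            measured[loc] = est
            counts[loc] = n
        k += len(batch)
        raw_est, current_est = _refresh_estimate(strategy, plan, grid, measured, normative, k)
        rows.append(
            {
                "k": k,
                "rmse": pointwise_rmse(truth, current_est),
                "rmse_raw": pointwise_rmse(truth, raw_est),
                "trials": int(sum(counts.values())),
            }
        )
    return TestResult(
        final_estimate=current_est,
        measured=measured,
        presentations=counts,
        trajectory=pd.DataFrame(rows),
    )


def _refresh_estimate(strategy, plan, grid, measured, normative, k):
    """(raw model estimate, measured-substituted estimate) after k locations."""
    if strategy.meta == "sors":
        raw = plan.estimate(measured, k=k, substitute=False)
        sub = raw.copy()
        sub[list(measured)] = [measured[i] for i in measured]
        return raw, sub
    if strategy.meta == "quadrant":
        raw = _quadrant_estimate(grid, measured, normative)
        return raw, raw  # growth map already substitutes measured values
    raw = normative.copy().astype(float)
    sub = raw.copy()
    sub[list(measured)] = [measured[i] for i in measured]
    return raw, sub


def __default_grid():
    from .grid import build_24_2_grid

    return build_24_2_grid()


# ---------------------------------------------------------------------------
# Cross-validated evaluation

@dataclass
class EvaluationReport:
    """Tidy per-field, per-checkpoint simulation results plus metadata."""

    records: pd.DataFrame  # fold, strategy, eye_id, field, md, severity, k, rmse, rmse_raw, trials
    scheme: str
    seed: int

    def mean_table(self) -> pd.DataFrame:
        """Mean RMSE and trials per strategy and checkpoint, across folds/fields."""
        return (
            self.records.groupby(["strategy", "k"])[["rmse", "rmse_raw", "trials"]]
            .mean()
            .reset_index()
        )

    def final_per_field(self) -> pd.DataFrame:
        idx = self.records.groupby(["strategy", "fold", "field"])["k"].idxmax()
        return self.records.loc[idx]

    def to_json(self, path) -> None:
        out = {
            "scheme": self.scheme,
            "seed": self.seed,
            "mean_table": self.mean_table().to_dict(orient="records"),
        }
        import json

        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


SCHEMES = {"small": (5, "train_one"), "large": (10, "train_rest")}


def _fold_eyes(dataset: FieldDataset, scheme: str, rng: np.random.Generator):
    n_folds, mode = SCHEMES[scheme]
    eyes = sorted(set(dataset.eye_ids))
    if len(eyes) < n_folds:
        raise ValueError(f"{scheme} scheme needs at least {n_folds} eyes, got {len(eyes)}")
    eyes = np.array(eyes)
    rng.shuffle(eyes)
    groups = np.array_split(eyes, n_folds)
    for i, g in enumerate(groups):
        if mode == "train_one":
            train = set(g)
            test = set(eyes) - train
        else:
            test = set(g)
            train = set(eyes) - test
        yield i, train, test


def crossvalidate(
    dataset: FieldDataset,
    strategies: dict[str, StrategyConfig],
    scheme: str = "small",
    seed: int = 0,
    max_test_fields_per_fold: int | None = None,
    max_folds: int | None = None,
) -> EvaluationReport:
    """Group-wise (by eye) cross-validated Monte Carlo evaluation.

    ``small`` = 5 folds training on 20% of eyes and testing on 80%;
    ``large`` = 10 folds training on 90% and testing on 10%.  Plans,
    priors and the normative hill are fitted on the training split of
    each fold only.  ``max_test_fields_per_fold``/``max_folds`` subsample
    the computation for quick studies; the fold structure is unchanged.
    """
    rng_folds = np.random.default_rng([seed % 2**31, 101])
    all_rows = []
    for fold, train_eyes, test_eyes in _fold_eyes(dataset, scheme, rng_folds):
        if max_folds is not None and fold >= max_folds:
            break
        train_cols = [j for j, e in enumerate(dataset.eye_ids) if e in train_eyes]
        test_cols = [j for j, e in enumerate(dataset.eye_ids) if e in test_eyes]
        assert not (set(train_eyes) & set(test_eyes))
        if max_test_fields_per_fold is not None:
            test_cols = test_cols[:max_test_fields_per_fold]
        train_ds = dataset.subset(train_cols)
        normative = normative_hill(train_ds)
        prior = build_prior(train_ds)
        plans: dict[str, SORSPlan | None] = {}
        for name, strat in strategies.items():
            if strat.meta == "sors":
                plans[name] = SORS(
                    train_ds,
                    reconstructor=strat.reconstructor,
                    n_components=strat.n_components,
                    max_prefix=strat.stop_after,
                ).fit()
            else:
                plans[name] = None
        for s_idx, (name, strat) in enumerate(strategies.items()):
            for j_idx, j in enumerate(test_cols):
                truth = dataset.X[:, j]
                rng = np.random.default_rng([seed % 2**31, fold, s_idx, j_idx])
                res = run_field_test(
                    strat, truth, prior, normative, rng, plan=plans[name], grid=dataset.grid
                )
                md = (
                    float(dataset.md[j])
                    if dataset.md is not None
                    else mean_deviation(truth, normative, dataset.grid)
                )
                for row in res.trajectory.to_dict(orient="records"):
                    all_rows.append(
                        {
                            "fold": fold,
                            "strategy": name,
                            "eye_id": dataset.eye_ids[j],
                            "field": j,
                            "md": md,
                            "severity": severity_class(md),
                            **row,
                        }
                    )
    return EvaluationReport(records=pd.DataFrame(all_rows), scheme=scheme, seed=seed)


def severity_stratify(report: EvaluationReport) -> pd.DataFrame:
    """Final-checkpoint RMSE and trials per severity group and strategy."""
    final = report.final_per_field()
    return (
        final.groupby(["strategy", "severity"])[["rmse", "trials"]]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def embedding_sweep(
    dataset: FieldDataset,
    n_values,
    scheme: str = "small",
    checkpoint: int = 36,
    seed: int = 0,
    kinds=("ttpcr",),
    max_folds: int | None = None,
    max_test_fields_per_fold: int | None = None,
) -> pd.DataFrame:
    """Train/test reconstruction RMSE at a checkpoint vs embedding dimension.

    For each embedding dimension a SORS plan is trained on each fold's
    training split and the reconstruction error after ``checkpoint``
    tested locations is evaluated with the true thresholds as the
    measured values (isolating reconstruction error from threshold-
    procedure noise).  At n = 54 both ttpcr and pls coincide with lr.
    """
    rng_folds = np.random.default_rng([seed % 2**31, 101])
    rows = []
    folds = list(_fold_eyes(dataset, scheme, rng_folds))
    if max_folds is not None:
        folds = folds[:max_folds]
    for fold, train_eyes, test_eyes in folds:
        train_cols = [j for j, e in enumerate(dataset.eye_ids) if e in train_eyes]
        test_cols = [j for j, e in enumerate(dataset.eye_ids) if e in test_eyes]
        if max_test_fields_per_fold is not None:
            test_cols = test_cols[:max_test_fields_per_fold]
        train_ds = dataset.subset(train_cols)
        for kind in kinds:
            for n in n_values:
                plan = SORS(
                    train_ds, reconstructor=kind, n_components=int(n), max_prefix=checkpoint
                ).fit()
                rows.append(
                    {
                        "fold": fold,
                        "kind": kind,
                        "n": int(n),
                        "train_rmse": _exact_rmse(plan, train_ds.X, checkpoint),
                        "test_rmse": _exact_rmse(plan, dataset.X[:, test_cols], checkpoint),
                    }
                )
    return pd.DataFrame(rows)


def _exact_rmse(plan: SORSPlan, M: np.ndarray, k: int) -> float:
    """RMSE of plan reconstruction at prefix k with true values as measurements."""
    errs = []
    for j in range(M.shape[1]):
        measured = {i: float(M[i, j]) for i in plan.order[:k]}
        est = plan.estimate(measured, k=k, substitute=True)
        errs.append(np.mean((est - M[:, j]) ** 2))
    return float(np.sqrt(np.mean(errs)))
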