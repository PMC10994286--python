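"""Sequentially Optimized Reconstruction Strategy (SORS) training.

SORS pre-computes, from a training dataset, (i) the order in which the 54
locations of the grid should be tested and (ii) one fitted reconstructor
per prefix length, so that at test time the whole field can be estimated
after any number of tested locations and the test terminated early.

Training is greedy: at each step, every remaining candidate location is
tentatively appended to the tested subset, a reconstructor is fitted on
the augmented subset, and the candidate whose model attains the lowest
training mean-squared error over the whole field is kept.  Ties break to
the lowest location index.  The greedy search does not guarantee the
globally optimal ordering (which would require exhaustive search over
permutations), but it is the defining procedure of the strategy.

Usage follows the model/results pattern::

    model = SORS(train_dataset, reconstructor="ttpcr", n_components=8)
    plan = model.fit()               # -> SORSPlan
    est = plan.estimate({12: 27.0, 40: 18.0, ...})
    print(plan.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fields import FieldDataset
from .grid import GridSpec, build_24_2_grid
from .reconstruction import (
    PCABasis,
    SubsetReconstructor,
    fit_mean,
    fit_pca,
    fit_reconstructor,
)


class SORS:
    """Greedy sequence-and-reconstructor trainer for one dataset.

    Parameters
    ----------
    dataset : FieldDataset
        Training fields (54 x N).
    reconstructor : {"lr", "ttpcr", "pls", "mean"}
        Reconstruction family fitted at every prefix.  ``mean`` yields the
        no-seeding baseline whose "order" is simply descending training
        variance.
    n_components : int
        Embedding dimension for ttpcr/pls (ignored by lr/mean).  For
        ttpcr the PCA basis is fitted once on the training targets before
        the greedy loop and frozen for all prefixes.
    max_prefix : int
        Train prefixes 1..max_prefix (default all 54); shorter plans train
        faster when the tail will never be used.
    """

    def __init__(
        self,
        dataset: FieldDataset,
        reconstructor: str = "ttpcr",
        n_components: int = 8,
        max_prefix: int | None = None,
    ):
        if dataset.n_fields < 2:
            raise ValueError("SORS training needs at least two fields")
        if reconstructor not in ("lr", "ttpcr", "pls", "mean"):
            raise ValueError(f"unknown reconstructor {reconstructor!r}")
        self.dataset = dataset
        self.reconstructor = reconstructor
        self.n_components = int(n_components)
        p = dataset.grid.n_locations
        self.max_prefix = int(max_prefix) if max_prefix else p
        if not 1 <= self.max_prefix <= p:
            raise ValueError(f"max_prefix must be in [1, {p}]")

    @classmethod
    def from_dataframe(cls, df, grid: GridSpec | None = None, **kwargs) -> "SORS":
        """Build from a wide DataFrame (eye_id + db_<x>_<y> columns)."""
        grid = grid or build_24_2_grid()
        cols = [f"db_{x}_{y}" for x, y in grid.locations]
        X = df[cols].to_numpy(dtype=float).T
        ids = [str(v) for v in df["eye_id"]]
        return cls(FieldDataset(X, ids, grid=grid), **kwargs)

    def fit(self) -> "SORSPlan":
        M = self.dataset.X
        p = M.shape[0]
        if np.allclose(M.std(axis=1), 0):
            import logging

            logging.getLogger(__name__).warning(
                "degenerate training data (constant fields); plan is arbitrary"
            )
        if self.reconstructor == "mean":
            return self._fit_mean_baseline()
        # fit_pca pads past the data rank with an orthonormal complement,
        # preserving the n=54 equivalence with plain linear regression even
        # when the training sample is smaller than the grid
        basis = (
            fit_pca(M, min(self.n_components, p))
            if self.reconstructor == "ttpcr"
            else None
        )
        order: list[int] = []
        models: list[SubsetReconstructor] = []
        curve: list[float] = []
        remaining = list(range(p))
        for _ in range(self.max_prefix):
            best = None  # (mse, candidate, model)
            for j in remaining:
                m = fit_reconstructor(
                    self.reconstructor, M, order + [j], n=self.n_components, basis=basis
                )
                mse = m.training_mse(M)
                if best is None or mse < best[0] - 1e-12 or (
                    abs(mse - best[0]) <= 1e-12 and j < best[1]
                ):
                    best = (mse, j, m)
            mse, j, m = best
            order.append(j)
            remaining.remove(j)
            models.append(m)
            curve.append(mse)
        return SORSPlan(
            order=tuple(order),
            models=models,
            kind=self.reconstructor,
            n_components=self.n_components if self.reconstructor in ("ttpcr", "pls") else None,
            training_curve=np.asarray(curve),
            basis=basis,
            n_train=M.shape[1],
            grid=self.dataset.grid,
        )

    def _fit_mean_baseline(self) -> "SORSPlan":
        M = self.dataset.X
        variances = M.var(axis=1)
        # descending variance, ties to lowest index (stable sort on -var)
        order = tuple(int(i) for i in np.argsort(-variances, kind="stable"))
        models = [fit_mean(M, order[:k]) for k in range(1, self.max_prefix + 1)]
        curve = np.asarray([m.training_mse(M) for m in models])
        return SORSPlan(
            order=order[: self.max_prefix],
            models=models,
            kind="mean",
            n_components=None,
            training_curve=curve,
            basis=None,
            n_train=M.shape[1],
            grid=self.dataset.grid,
        )


@dataclass
class SORSPlan:
    """Fitted SORS results: the test order and one model per prefix length."""

    order: tuple[int, ...]
    models: list[SubsetReconstructor]
    kind: str
    n_components: int | None
    training_curve: np.ndarray
    basis: PCABasis | None
    n_train: int
    grid: GridSpec = field(default_factory=build_24_2_grid)

    def __post_init__(self):
        if len(set(self.order)) != len(self.order):
            raise ValueError("order must not repeat locations")
        for k, m in enumerate(self.models, start=1):
            if tuple(m.subset) != tuple(self.order[:k]):
                raise ValueError(f"model {k} subset does not match order prefix")

    @property
    def max_prefix(self) -> int:
        return len(self.models)

    def estimate(
        self, measured: dict[int, float], k: int | None = None, substitute: bool = True
    ) -> np.ndarray:
        """Full-field estimate from the measured prefix values.

        ``measured`` must cover exactly the first ``k`` locations of the
        order (k defaults to len(measured)).  With ``substitute`` the
        measured values overwrite the model output at tested locations —
        the reconstruction fills in only the untested ones.
        """
        k = len(measured) if k is None else k
        if not 1 <= k <= self.max_prefix:
            raise ValueError(f"k must be in [1, {self.max_prefix}]")
        prefix = self.order[:k]
        if set(measured) != set(prefix):
            raise ValueError("measured keys must be exactly the first k order locations")
        s = np.array([measured[i] for i in prefix], dtype=float)
        est = self.models[k - 1].predict(s, clip=True)
        if substitute:
            est = est.copy()
            est[list(prefix)] = s
        return est

    def sequence_map(self) -> list[tuple[int, int, int]]:
        """(x, y, rank) triples, rank 1..len(order), for plotting the order."""
        return [
            (self.grid.locations[i][0], self.grid.locations[i][1], r + 1)
            for r, i in enumerate(self.order)
        ]

    def summary(self) -> str:
        lines = [
            "SORS plan",
            "=" * 44,
            f"reconstructor:      {self.kind}"
            + (f" (n={self.n_components})" if self.n_components else ""),
            f"training fields:    {self.n_train}",
            f"prefix lengths:     1..{self.max_prefix}",
            "",
            "first locations (x, y):",
        ]
        coords = [str(self.grid.locations[i]) for i in self.order[:8]]
        lines.append("  " + ", ".join(coords))
        lines.append("")
        lines.append("training RMSE (dB) by tested locations:")
        for k in (1, 4, 8, 16, 24, 36, 46, 54):
            if k <= self.max_prefix:
                lines.append(f"  k={k:2d}: {np.sqrt(self.training_curve[k - 1]):6.3f}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        d = {
            "kind": self.kind,
            "n_components": self.n_components,
            "n_train": self.n_train,
            "order": list(self.order),
            "training_curve": self.training_curve.tolist(),
            "grid": json.loads(self.grid.to_json()),
            "basis": None
            if self.basis is None
            else {
                "mu": self.basis.mu.tolist(),
                "components": self.basis.components.tolist(),
                "eigenvalues": self.basis.eigenvalues.tolist(),
            },
            "models": [
                {
                    "kind": m.kind,
                    "subset": list(m.subset),
                    "D": m.D.tolist(),
                    "beta": m.beta.tolist(),
                    "n": m.n,
                }
                for m in self.models
            ],
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def load(cls, path) -> "SORSPlan":
        with open(path) as fh:
            d = json.load(fh)
        grid = GridSpec(
            locations=tuple(tuple(p) for p in d["grid"]["locations"]),
            blind_spot=frozenset(d["grid"]["blind_spot"]),
        )
        basis = None
        if d["basis"] is not None:
            basis = PCABasis(
                mu=np.asarray(d["basis"]["mu"]),
                components=np.asarray(d["basis"]["components"]),
                eigenvalues=np.asarray(d["basis"]["eigenvalues"]),
            )
        models = [
            SubsetReconstructor(
                kind=m["kind"],
                subset=tuple(m["subset"]),
                D=np.asarray(m["D"]),
                beta=np.asarray(m["beta"]),
                n=m["n"],
                basis=basis if m["kind"] == "ttpcr" else None,
            )
            for m in d["models"]
        ]
        return cls(
            order=tuple(d["order"]),
            models=models,
            kind=d["kind"],
            n_components=d["n_components"],
            training_curve=np.asarray(d["training_curve"]),
            basis=basis,
            n_train=d["n_train"],
            grid=grid,
        )


def train_sors(
    dataset: FieldDataset,
    kind: str = "ttpcr",
    n_components: int = 8,
    max_prefix: int | None = None,
) -> SORSPlan:
    """Functional wrapper over ``SORS(...).fit()``."""
    return SORS(
        dataset, reconstructor=kind, n_components=n_components, max_prefix=max_prefix
    ).fit()


def plan_estimate(
    plan: SORSPlan, measured: dict[int, float], k: int | None = None, substitute: bool = True
) -> np.ndarray:
    """Functional wrapper over ``SORSPlan.estimate``."""
    return plan.estimate(measured, k=k, substitute=substitute)


def sequence_map(plan: SORSPlan, grid: GridSpec | None = None):
    """Functional wrapper over ``SORSPlan.sequence_map``."""
    return plan.sequence_map()
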