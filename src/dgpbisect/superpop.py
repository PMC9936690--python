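"""Super-population covariate generation.

Every calibration simulates a large cohort of baseline covariates once and
freezes it: the bisection iterations then re-simulate only the outcomes, so
Monte Carlo noise in the evaluator comes from the outcome draws alone.  The
default covariate family is independent standard normals plus independent
Bernoulli indicators, but a caller-supplied column generator makes the
calibration machinery distribution-agnostic.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import SpecificationError

__all__ = ["CovariateSpec", "SuperPopulation", "generate_superpopulation"]

CONTINUOUS = "continuous"
BINARY = "binary"

ColumnGenerator = Callable[[np.random.Generator, "CovariateSpec"], np.ndarray]


@dataclasses.dataclass(frozen=True)
class CovariateSpec:
    """Layout of the simulated baseline covariates.

    Parameters
    ----------
    n_continuous : int
        Number of independent standard-normal columns.
    n_binary : int
        Number of independent Bernoulli columns.
    binary_p : float
        Success probability of each Bernoulli column, in (0, 1).
    population_size : int
        Number of subjects N in the super-population.  Large N (default 10⁶)
        makes empirical summaries approximate population quantities.
    """

    n_continuous: int = 5
    n_binary: int = 5
    binary_p: float = 0.5
    population_size: int = 1_000_000

    def __post_init__(self) -> None:
        if int(self.n_continuous) < 0 or int(self.n_binary) < 0:
            raise SpecificationError("covariate counts must be nonnegative")
        if int(self.n_continuous) + int(self.n_binary) < 1:
            raise SpecificationError("at least one covariate is required")
        if not 0.0 < float(self.binary_p) < 1.0:
            raise SpecificationError("binary_p must lie strictly in (0, 1)")
        if int(self.population_size) < 1:
            raise SpecificationError("population_size must be >= 1")

    @property
    def n_covariates(self) -> int:
        return int(self.n_continuous) + int(self.n_binary)


@dataclasses.dataclass(frozen=True)
class SuperPopulation:
    """An N×p matrix of baseline covariates with per-column role labels."""

    values: np.ndarray
    column_roles: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise SpecificationError("covariate values must form a 2-D matrix")
        if values.shape[1] != len(self.column_roles):
            raise SpecificationError(
                f"{values.shape[1]} columns but {len(self.column_roles)} role labels"
            )
        for j, role in enumerate(self.column_roles):
            if role == BINARY:
                col = values[:, j]
                if not np.isin(col, (0.0, 1.0)).all():
                    raise SpecificationError(f"binary column {j} contains values other than 0/1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "column_roles", tuple(self.column_roles))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> tuple[str, ...]:
        counts: dict[str, int] = {}
        names = []
        for role in self.column_roles:
            counts[role] = counts.get(role, 0) + 1
            names.append(f"{role}_{counts[role]}")
        return tuple(names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.column_names))

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def generate_superpopulation(
    spec: CovariateSpec,
    seed: int | np.random.Generator,
    column_generator: ColumnGenerator | None = None,
) -> SuperPopulation:
    """Simulate the super-population of baseline covariates.

    Continuous columns are independent standard-normal draws and binary
    columns independent Bernoulli(``spec.binary_p``) draws, generated in that
    order; identical ``(spec, seed)`` pairs yield bitwise-identical matrices.

    ``column_generator(rng, spec) -> values`` overrides the default family
    entirely (the calibration machinery is agnostic to the covariate
    distribution); it must return an ``(N, p)`` matrix matching ``spec``'s
    column count, and columns it labels binary must contain only 0/1.  When a
    generator is supplied, all of its columns are labelled ``"continuous"``
    unless the matrix column is exactly 0/1-valued, which is labelled
    ``"binary"``.
    """
    rng = np.random.default_rng(seed)
    n = int(spec.population_size)
    if column_generator is not None:
        values = np.asarray(column_generator(rng, spec), dtype=np.float64)
        if values.shape != (n, spec.n_covariates):
            raise SpecificationError(
                f"column generator returned shape {values.shape}, "
                f"expected {(n, spec.n_covariates)}"
            )
        roles = tuple(
            BINARY if np.isin(values[:, j], (0.0, 1.0)).all() else CONTINUOUS
            for j in range(values.shape[1])
        )
        return SuperPopulation(values=values, column_roles=roles)

    values = np.empty((n, spec.n_covariates), dtype=np.float64)
    k = int(spec.n_continuous)
    if k:
        values[:, :k] = rng.standard_normal((n, k))
    if spec.n_binary:
        values[:, k:] = rng.random((n, int(spec.n_binary))) < float(spec.binary_p)
    roles = (CONTINUOUS,) * k + (BINARY,) * int(spec.n_binary)
    return SuperPopulation(values=values, column_roles=roles)
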