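"""Population-based topological-map model of hippocampal temporal memory.

Hippocampal "time cells" fire selectively at specific moments of a timed
interval; the width of each cell's Gaussian firing field grows in proportion
to its peak time.  This module implements a population model in which such
cells, arranged in a spatially ordered (ventral -> dorsal = short -> long)
map, are combined by learned weights into an *average time field* whose peak
approximates a to-be-learned criterion time ``T``.

The model, in the field's standard notation:

* single-cell firing field    ``a_n(t) = A_n * exp(-(t - t_n)^2 / (2 sigma_n^2))``
  with ``sigma_n = cv * t_n`` (scalar widths);
* average time field          ``a(t) = sum_k A_k * exp(-(t - t_k)^2 / (2 sigma_k^2))``;
* error signal                ``err_k = |T - t_k| + epsilon``;
* learning rule (per trial)   ``A_k <- A_k / err_k``.

Iterating the rule gives the closed form ``A_k(n) = A_0 / (|T - t_k| + eps)^n``
— a power-law decay of weight with temporal distance from the criterion,
which serves as the independent oracle for the trial-by-trial trainer.

The file is organised in the order the method runs: configuration defaults,
population construction and lesioning, the learning rule, field analysis
(peak / half-width / scalar-property diagnostics), and simulation I/O for
the command-line interface.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    # configuration defaults
    "CV_DEFAULT",
    "EPSILON_DEFAULT",
    "BOUNDARY_FACTOR_DEFAULT",
    "INITIAL_WEIGHT_DEFAULT",
    # errors
    "InvalidConfigError",
    "EmptyPopulationError",
    "DegenerateFieldError",
    # population
    "TimeCell",
    "Population",
    "LesionSide",
    "make_uniform_population",
    "make_fixture_population",
    "FIXTURE_PEAK_TIMES",
    "firing_rate",
    "lesion",
    # learning
    "LearningConfig",
    "error_signal",
    "apply_trial",
    "train",
    "closed_form_weights",
    "train_multi",
    # field analysis
    "TimeGrid",
    "TimeField",
    "WidthReport",
    "ScalarRegime",
    "average_time_field",
    "measure_width",
    "width_cell",
    "width_learn",
    "scalar_regime",
    "scalar_report",
    "timing_error",
    # simulation I/O
    "SimulationSpec",
    "run_simulate",
    "run_scalar",
    "run_lesion",
]

logger = logging.getLogger("timecellmap")

# --------------------------------------------------------------------------
# Configuration defaults
# --------------------------------------------------------------------------

#: Width/peak-time proportionality constant sigma_k = cv * t_k.  Recordings
#: constrain the *proportionality*, not its value; 0.2 gives fields for which
#: the sparse five-cell example peaks near 8 s and the Fig.-2-style fixtures
#: produce a single-bump envelope.
CV_DEFAULT: float = 0.2

#: Regularising offset in the error signal err_k = |T - t_k| + epsilon (s).
#: 0.5 s reproduces the published two-trial weight sequence exactly
#: (e.g. 1/(|10-8|+0.5) = 0.4).
EPSILON_DEFAULT: float = 0.5

#: The population's temporal boundary is this multiple of the criterion time,
#: mirroring how boundary-anchored place fields tile an enclosure.
BOUNDARY_FACTOR_DEFAULT: float = 3.0

#: All cells start with the same maximum firing rate A_0.
INITIAL_WEIGHT_DEFAULT: float = 1.0


class InvalidConfigError(ValueError):
    """A model parameter violates its precondition."""


class EmptyPopulationError(ValueError):
    """An operation that needs at least one time cell received none."""


class DegenerateFieldError(ValueError):
    """A width measurement was requested on a constant (flat) field."""


# --------------------------------------------------------------------------
# Population: Gaussian time cells on an ordered ventral->dorsal map
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeCell:
    """One Gaussian temporal receptive field.

    Parameters
    ----------
    peak_time
        Time of maximal firing t_n, seconds; must be positive.
    sigma
        Field width sigma_n, seconds; must be positive.  Generator-built
        cells satisfy ``sigma = cv * peak_time``.
    weight
        Maximum firing rate A_n (dimensionless, non-negative); this is the
        quantity the learning rule updates.
    """

    peak_time: float
    sigma: float
    weight: float = INITIAL_WEIGHT_DEFAULT

    def __post_init__(self) -> None:
        if not (self.peak_time > 0):
            raise InvalidConfigError(f"peak_time must be > 0, got {self.peak_time}")
        if not (self.sigma > 0):
            raise InvalidConfigError(f"sigma must be > 0, got {self.sigma}")
        if not (self.weight >= 0):
            raise InvalidConfigError(f"weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class Population:
    """Spatially ordered collection of time cells.

    Cells are stored strictly sorted by ``peak_time``; index 0 is the most
    ventral cell (shortest duration), the last index the most dorsal
    (longest).  ``boundary`` is the upper end of the covered peak times and
    ``cv`` the width/peak-time proportionality constant used to build the
    cells.  Populations are immutable; every operation returns a new one.
    """

    cells: tuple[TimeCell, ...]
    boundary: float
    cv: float = CV_DEFAULT

    def __post_init__(self) -> None:
        peaks = [c.peak_time for c in self.cells]
        if any(b <= a for a, b in zip(peaks, peaks[1:])):
            raise InvalidConfigError("cells must be strictly sorted by peak_time")
        # tiny relative slack: generators build peaks as fractions of the
        # boundary and the top cell may land one ulp above it
        tol = self.boundary * 1e-12
        if self.cells and not all(0 < p <= self.boundary + tol for p in peaks):
            raise InvalidConfigError(
                f"all peak times must lie in (0, {self.boundary}]"
            )
        if not (self.cv > 0):
            raise InvalidConfigError(f"cv must be > 0, got {self.cv}")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([c.peak_time for c in self.cells])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c.sigma for c in self.cells])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.cells])

    def with_weights(self, weights: Iterable[float]) -> "Population":
        """Return a copy with the given weights (same order), peaks/sigmas unchanged."""
        weights = list(weights)
        if len(weights) != len(self.cells):
            raise InvalidConfigError(
                f"expected {len(self.cells)} weights, got {len(weights)}"
            )
        cells = tuple(
            replace(c, weight=float(w)) for c, w in zip(self.cells, weights)
        )
        return replace(self, cells=cells)

    def normalized_weights(self) -> np.ndarray:
        """Weights divided by their sum (a presentation view, never applied internally)."""
        w = self.weights
        total = w.sum()
        if total == 0:
            raise InvalidConfigError("cannot normalize an all-zero weight vector")
        return w / total

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: ``cell_index,peak_time_s,sigma_s,weight``, ventral->dorsal."""
        return pd.DataFrame(
            {
                "cell_index": np.arange(len(self.cells)),
                "peak_time_s": self.peak_times,
                "sigma_s": self.sigmas,
                "weight": self.weights,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, cv: float = CV_DEFAULT) -> "Population":
        df = pd.read_csv(path)
        cells = tuple(
            TimeCell(peak_time=row.peak_time_s, sigma=row.sigma_s, weight=row.weight)
            for row in df.itertuples()
        )
        boundary = max((c.peak_time for c in cells), default=0.0)
        return cls(cells=cells, boundary=boundary, cv=cv)


class LesionSide(str, enum.Enum):
    """End of the ventral->dorsal map a lesion removes cells from."""

    VENTRAL = "ventral"  # shortest peak times
    DORSAL = "dorsal"    # longest peak times


def make_uniform_population(
    criterion: float,
    n_cells: int,
    boundary_factor: float = BOUNDARY_FACTOR_DEFAULT,
    cv: float = CV_DEFAULT,
    initial_weight: float = INITIAL_WEIGHT_DEFAULT,
) -> Population:
    """Uniformly tile ``(0, boundary_factor * criterion]`` with time cells.

    Peak times sit on the grid ``t_i = i * boundary / n_cells`` for
    ``i = 1..n_cells`` (no cell at t = 0, where sigma = cv*t would
    degenerate), each with ``sigma = cv * t_i`` and weight ``initial_weight``.
    """
    if not (criterion > 0):
        raise InvalidConfigError(f"criterion must be > 0, got {criterion}")
    if n_cells < 2:
        raise InvalidConfigError(f"n_cells must be >= 2, got {n_cells}")
    if not (boundary_factor > 1):
        raise InvalidConfigError(
            f"boundary_factor must be > 1, got {boundary_factor}"
        )
    if not (cv > 0):
        raise InvalidConfigError(f"cv must be > 0, got {cv}")
    boundary = boundary_factor * criterion
    # t_i = i/n * boundary: the last cell sits exactly on the boundary
    peaks = boundary * np.arange(1, n_cells + 1) / n_cells
    cells = tuple(
        TimeCell(peak_time=float(t), sigma=float(cv * t), weight=initial_weight)
        for t in peaks
    )
    return Population(cells=cells, boundary=boundary, cv=cv)


#: Peak times (s) of the hand-placed example configurations used throughout
#: the docs and tests: two symmetric five-cell sets bracketing criteria of
#: 10 s and 30 s, and a sparse asymmetric set whose nearest cell to T = 10 s
#: sits 2 s away.
FIXTURE_PEAK_TIMES: dict[str, tuple[float, ...]] = {
    "fig2_T10": (4.0, 6.0, 8.0, 12.0, 14.0),
    "fig2_T30": (12.0, 18.0, 24.0, 36.0, 42.0),
    "sparse_T10": (6.0, 8.0, 12.0, 20.0, 30.0),
}


def make_fixture_population(name: str, cv: float = CV_DEFAULT) -> Population:
    """Build one of the named example configurations (see FIXTURE_PEAK_TIMES)."""
    try:
        peaks = FIXTURE_PEAK_TIMES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURE_PEAK_TIMES)}"
        ) from None
    cells = tuple(
        TimeCell(peak_time=t, sigma=cv * t, weight=INITIAL_WEIGHT_DEFAULT)
        for t in peaks
    )
    return Population(cells=cells, boundary=max(peaks), cv=cv)


def firing_rate(cell: TimeCell, t: float | np.ndarray) -> float | np.ndarray:
    """Gaussian firing rate of one cell at time(s) ``t``.

    ``A_n * exp(-(t - t_n)^2 / (2 sigma_n^2))``; defined for all finite t,
    bounded by ``[0, weight]`` and symmetric about the peak.
    """
    t = np.asarray(t, dtype=float)
    out = cell.weight * np.exp(-((t - cell.peak_time) ** 2) / (2.0 * cell.sigma**2))
    return float(out) if out.ndim == 0 else out


def lesion(pop: Population, side: LesionSide | str, fraction: float) -> Population:
    """Ablate ``floor(fraction * N)`` cells from one end of the ordered map.

    ``ventral`` removes the cells with the smallest peak times, ``dorsal``
    the largest; surviving weights are untouched and a new Population is
    returned (the input is never modified).  A full lesion (fraction = 1)
    yields an empty population, which downstream field operations reject.
    """
    side = LesionSide(side)
    if not (0.0 <= fraction <= 1.0):
        raise InvalidConfigError(f"lesion fraction must be in [0, 1], got {fraction}")
    n_removed = math.floor(fraction * len(pop.cells))
    if n_removed == 0:
        return pop
    if side is LesionSide.VENTRAL:
        survivors = pop.cells[n_removed:]
    else:
        survivors = pop.cells[: len(pop.cells) - n_removed]
    boundary = survivors[-1].peak_time if survivors else pop.boundary
    return Population(cells=survivors, boundary=boundary, cv=pop.cv)


# --------------------------------------------------------------------------
# Learning: error signal and multiplicative weight updates
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LearningConfig:
    """Parameters of one training run toward a single criterion time.

    ``criterion`` is the to-be-learned duration T (s); ``epsilon`` the
    regularising offset in the error signal (s, > 0 — it removes the
    division singularity at t_k = T); ``n_trials`` the number of learning
    trials; ``initial_weight`` the common starting amplitude A_0.
    """

    criterion: float
    epsilon: float = EPSILON_DEFAULT
    n_trials: int = 1
    initial_weight: float = INITIAL_WEIGHT_DEFAULT

    def __post_init__(self) -> None:
        if not (self.criterion > 0):
            raise InvalidConfigError(f"criterion must be > 0, got {self.criterion}")
        if not (self.epsilon > 0):
            raise InvalidConfigError(f"epsilon must be > 0, got {self.epsilon}")
        if self.n_trials < 1:
            raise InvalidConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if not (self.initial_weight > 0):
            raise InvalidConfigError(
                f"initial_weight must be > 0, got {self.initial_weight}"
            )


def error_signal(
    criterion: float, peak_time: float | np.ndarray, epsilon: float
) -> float | np.ndarray:
    """Error ``err_k = |T - t_k| + epsilon`` (s); strictly positive."""
    if not (epsilon > 0):
        raise InvalidConfigError(f"epsilon must be > 0, got {epsilon}")
    peak_time = np.asarray(peak_time, dtype=float)
    out = np.abs(criterion - peak_time) + epsilon
    return float(out) if out.ndim == 0 else out


def apply_trial(pop: Population, cfg: LearningConfig) -> Population:
    """One learning trial: every weight becomes ``A_k / (|T - t_k| + eps)``.

    Peak times, widths and ordering are untouched; cells closer to the
    criterion are divided by a smaller error and so end up relatively
    stronger.
    """
    if len(pop) == 0:
        raise EmptyPopulationError("cannot train an empty population")
    errs = error_signal(cfg.criterion, pop.peak_times, cfg.epsilon)
    return pop.with_weights(pop.weights / errs)


def train(
    pop: Population, cfg: LearningConfig
) -> tuple[Population, pd.DataFrame]:
    """Run ``cfg.n_trials`` learning trials.

    Returns the final population and the full weight trajectory as a long
    table ``trial,cell_index,peak_time_s,weight`` with ``n_trials + 1``
    trial blocks, trial 0 being the initial state.
    """
    if len(pop) == 0:
        raise EmptyPopulationError("cannot train an empty population")
    history = [pop.weights]
    current = pop
    for trial in range(cfg.n_trials):
        current = apply_trial(current, cfg)
        logger.info(
            "trial %d: max weight %.4g at t=%.3g s",
            trial + 1,
            current.weights.max(),
            current.peak_times[int(np.argmax(current.weights))],
        )
        history.append(current.weights)
    n_cells = len(pop)
    frame = pd.DataFrame(
        {
            "trial": np.repeat(np.arange(cfg.n_trials + 1), n_cells),
            "cell_index": np.tile(np.arange(n_cells), cfg.n_trials + 1),
            "peak_time_s": np.tile(pop.peak_times, cfg.n_trials + 1),
            "weight": np.concatenate(history),
        }
    )
    return current, frame


def closed_form_weights(
    peak_times: Sequence[float] | np.ndarray, cfg: LearningConfig
) -> np.ndarray:
    """Analytic weights after ``cfg.n_trials`` trials.

    Iterating the multiplicative rule gives
    ``A_k(n) = A_0 / (|T - t_k| + eps)^n`` — the independent oracle against
    which the trial-by-trial trainer is checked.
    """
    errs = error_signal(cfg.criterion, np.asarray(peak_times, dtype=float), cfg.epsilon)
    return cfg.initial_weight * np.asarray(errs) ** (-float(cfg.n_trials))


def train_multi(
    pop: Population,
    criteria: Sequence[float],
    trials_per_criterion: int = 1,
    epsilon: float = EPSILON_DEFAULT,
) -> Population:
    """Train toward several criteria in sequence, carrying weights forward.

    No reset or renormalisation occurs between criteria, so cells at
    previously learned criteria keep elevated weights: after training
    T1 then T2 with cells at exactly those times, both hold the weight
    ``A_0 / ((|T1 - T2| + eps) * eps)`` and tie for the population maximum.
    """
    if len(criteria) == 0:
        raise InvalidConfigError("need at least one criterion")
    current = pop
    for criterion in criteria:
        cfg = LearningConfig(
            criterion=criterion,
            epsilon=epsilon,
            n_trials=trials_per_criterion,
            initial_weight=INITIAL_WEIGHT_DEFAULT,
        )
        current, _ = train(current, cfg)
    return current


# --------------------------------------------------------------------------
# Field analysis: average time field, half-widths, scalar-property regime
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid for the (continuous) average time field."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if not (self.start < self.stop):
            raise InvalidConfigError("grid start must be < stop")
        if not (self.step > 0):
            raise InvalidConfigError("grid step must be > 0")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    @classmethod
    def for_population(
        cls, pop: Population, criterion: float | None = None
    ) -> "TimeGrid":
        """Default analysis grid: step = criterion/1000 over [0, boundary].

        The 0.1% relative step keeps the peak-location error negligible at
        no meaningful runtime cost.
        """
        ref = criterion if criterion is not None else pop.boundary / BOUNDARY_FACTOR_DEFAULT
        return cls(start=0.0, stop=float(pop.boundary), step=float(ref) / 1000.0)


@dataclass(frozen=True)
class TimeField:
    """Average time field sampled on a grid; values are non-negative amplitudes."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.times.shape:
            raise InvalidConfigError("field values must match the grid length")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise InvalidConfigError("field values must be finite and >= 0")
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.grid.times, "amplitude": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class WidthReport:
    """Peak location and half-maximum widths of a time field.

    ``half_width_left``/``right`` are the distances from the peak to the
    half-maximum crossings on each side (NaN if the field never drops to
    half maximum inside the grid on that side); ``half_width_mean``
    averages the defined sides.
    """

    peak_time: float
    peak_value: float
    half_width_left: float
    half_width_right: float
    half_width_mean: float

    def to_dict(self) -> dict[str, float | None]:
        def _clean(x: float) -> float | None:
            return None if math.isnan(x) else x

        return {
            "peak_time": self.peak_time,
            "peak_value": self.peak_value,
            "half_width_left": _clean(self.half_width_left),
            "half_width_right": _clean(self.half_width_right),
            "half_width_mean": self.half_width_mean,
        }


class ScalarRegime(str, enum.Enum):
    """Which mechanism sets the average field's width."""

    SCALAR = "scalar"                    # cell widths dominate: Weber-like timing
    LEARNING_LIMITED = "learning_limited"  # epsilon dominates: constant width


def average_time_field(pop: Population, grid: TimeGrid) -> TimeField:
    """Weighted sum of all cells' Gaussians sampled on ``grid``.

    ``a(t_i) = sum_k A_k exp(-(t_i - t_k)^2 / (2 sigma_k^2))``; linear in
    the weights.
    """
    if len(pop) == 0:
        raise EmptyPopulationError("cannot evaluate the field of an empty population")
    t = grid.times[:, None]
    values = np.sum(
        pop.weights[None, :]
        * np.exp(-((t - pop.peak_times[None, :]) ** 2) / (2.0 * pop.sigmas[None, :] ** 2)),
        axis=1,
    )
    return TimeField(grid=grid, values=values)


def _half_crossing(
    times: np.ndarray, values: np.ndarray, peak_idx: int, half: float, direction: int
) -> float:
    """Distance from the peak to the first half-maximum crossing on one side.

    Walks outward from the peak (direction -1 = left, +1 = right) and
    linearly interpolates between the bracketing samples; NaN if the field
    never reaches half maximum inside the grid on that side.
    """
    i = peak_idx
    while 0 <= i + direction < len(values):
        j = i + direction
        if values[j] <= half:
            # interpolate between samples i (above) and j (at/below)
            if values[i] == values[j]:
                t_cross = times[j]
            else:
                frac = (values[i] - half) / (values[i] - values[j])
                t_cross = times[i] + frac * (times[j] - times[i])
            return abs(t_cross - times[peak_idx])
        i = j
    return float("nan")


def measure_width(field: TimeField) -> WidthReport:
    """Locate the field maximum and its half-maximum half-widths.

    The peak is the grid argmax (ties broken toward the smaller time); each
    half-width is the distance to the first crossing of ``peak_value / 2``
    on that side, linearly interpolated between grid samples.  A side that
    never drops to half maximum inside the grid is reported as NaN and the
    mean uses the defined side(s) only.
    """
    values = field.values
    if np.all(values == values[0]):
        raise DegenerateFieldError("cannot measure the width of a constant field")
    times = field.grid.times
    peak_idx = int(np.argmax(values))  # argmax returns the first (smallest-time) tie
    peak_value = float(values[peak_idx])
    half = peak_value / 2.0
    left = _half_crossing(times, values, peak_idx, half, direction=-1)
    right = _half_crossing(times, values, peak_idx, half, direction=+1)
    sides = [w for w in (left, right) if not math.isnan(w)]
    mean = float(np.mean(sides)) if sides else float("nan")
    return WidthReport(
        peak_time=float(times[peak_idx]),
        peak_value=peak_value,
        half_width_left=left,
        half_width_right=right,
        half_width_mean=mean,
    )


def width_cell(sigma: float) -> float:
    """Intrinsic half-width of a single Gaussian field: ``sigma * sqrt(2 ln 2)``."""
    if not (sigma > 0):
        raise InvalidConfigError(f"sigma must be > 0, got {sigma}")
    return sigma * math.sqrt(2.0 * math.log(2.0))


def width_learn(epsilon: float) -> float:
    """Half-width of the learned weight profile.

    The weight profile ``1 / (|T - t| + eps)`` peaks at ``1/eps`` and falls
    to half that value at distance ``|T - t| = eps``, so the learning rule
    alone contributes a half-width of exactly ``epsilon``.
    """
    if not (epsilon > 0):
        raise InvalidConfigError(f"epsilon must be > 0, got {epsilon}")
    return epsilon


def scalar_regime(sigma_at_criterion: float, epsilon: float) -> ScalarRegime:
    """Classify which contribution dominates the average field's width.

    ``scalar`` iff the intrinsic cell half-width strictly exceeds the
    learning half-width (``sigma * sqrt(2 ln 2) > eps``): the field then
    inherits the cells' proportional widths and timing is Weber-like.
    Otherwise the width is pinned at ~epsilon regardless of the criterion
    (``learning_limited``).  The tie goes to ``learning_limited``.
    """
    if (
        width_cell(sigma_at_criterion) > width_learn(epsilon)
    ):
        return ScalarRegime.SCALAR
    return ScalarRegime.LEARNING_LIMITED


def timing_error(pop: Population, criterion: float) -> float:
    """Best achievable timing accuracy: ``min_k |T - t_k|`` (s).

    The learning rule favours the nearest available cell, so the distance
    to that cell bounds how close the trained field's peak can sit to T.
    """
    if len(pop) == 0:
        raise EmptyPopulationError("timing error undefined for an empty population")
    return float(np.min(np.abs(criterion - pop.peak_times)))


def scalar_report(
    criteria: Sequence[float],
    n_cells: int = 100,
    boundary_factor: float = BOUNDARY_FACTOR_DEFAULT,
    cv: float = CV_DEFAULT,
    epsilon: float = EPSILON_DEFAULT,
    n_trials: int = 1,
    scale_epsilon: bool = False,
) -> pd.DataFrame:
    """Run the full pipeline per criterion and tabulate the scalar property.

    Each criterion gets the same *relative* configuration (n_cells,
    boundary_factor, cv, trials).  With ``scale_epsilon`` the regularising
    offset scales with the criterion (``eps_T = eps * T / criteria[0]``),
    making the whole pipeline exactly scale-covariant; with a fixed epsilon
    the width ratios deviate from the criterion ratios only through the
    epsilon-induced term.

    Returns a table with columns ``criterion, peak_time, half_width_left,
    half_width_right, half_width_mean, width_over_criterion, width_ratio``
    (widths s; ``width_ratio`` is relative to the first criterion's width).
    """
    if len(criteria) < 2:
        raise InvalidConfigError("scalar analysis needs at least two criteria")
    rows = []
    for criterion in criteria:
        eps = epsilon * criterion / criteria[0] if scale_epsilon else epsilon
        pop = make_uniform_population(
            criterion, n_cells, boundary_factor=boundary_factor, cv=cv
        )
        cfg = LearningConfig(criterion=criterion, epsilon=eps, n_trials=n_trials)
        trained, _ = train(pop, cfg)
        grid = TimeGrid.for_population(trained, criterion=criterion)
        report = measure_width(average_time_field(trained, grid))
        rows.append(
            {
                "criterion": criterion,
                "peak_time": report.peak_time,
                "half_width_left": report.half_width_left,
                "half_width_right": report.half_width_right,
                "half_width_mean": report.half_width_mean,
                "width_over_criterion": report.half_width_mean / criterion,
            }
        )
    df = pd.DataFrame(rows)
    df["width_ratio"] = df["half_width_mean"] / df["half_width_mean"].iloc[0]
    return df


# --------------------------------------------------------------------------
# Simulation I/O: validated specs, artifact writing, run manifests
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationSpec:
    """Fully validated parameter set for one simulation run.

    ``fixture`` (one of the named example configurations) overrides the
    uniform generator; otherwise a uniform population of ``n_cells`` over
    ``(0, boundary_factor * criterion]`` is built.  ``grid_step`` defaults
    to criterion/1000.  ``lesion_side``/``lesion_fraction`` are only used
    by the lesion pipeline.
    """

    criterion: float
    n_cells: int = 100
    fixture: str | None = None
    boundary_factor: float = BOUNDARY_FACTOR_DEFAULT
    cv: float = CV_DEFAULT
    epsilon: float = EPSILON_DEFAULT
    n_trials: int = 1
    grid_step: float | None = None
    lesion_side: str | None = None
    lesion_fraction: float = 0.0

    def __post_init__(self) -> None:
        # LearningConfig and the generators re-validate; fail fast here so a
        # bad spec never starts computing.
        LearningConfig(
            criterion=self.criterion, epsilon=self.epsilon, n_trials=self.n_trials
        )
        if self.fixture is not None and self.fixture not in FIXTURE_PEAK_TIMES:
            raise InvalidConfigError(
                f"unknown fixture {self.fixture!r}; choose from {sorted(FIXTURE_PEAK_TIMES)}"
            )
        if self.fixture is None:
            if self.n_cells < 2:
                raise InvalidConfigError(f"n_cells must be >= 2, got {self.n_cells}")
            if not (self.boundary_factor > 1):
                raise InvalidConfigError(
                    f"boundary_factor must be > 1, got {self.boundary_factor}"
                )
        if not (self.cv > 0):
            raise InvalidConfigError(f"cv must be > 0, got {self.cv}")
        if self.grid_step is not None and not (self.grid_step > 0):
            raise InvalidConfigError(f"grid_step must be > 0, got {self.grid_step}")
        if self.lesion_side is not None:
            LesionSide(self.lesion_side)
        if not (0.0 <= self.lesion_fraction <= 1.0):
            raise InvalidConfigError(
                f"lesion_fraction must be in [0, 1], got {self.lesion_fraction}"
            )

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "SimulationSpec":
        """Load a spec from a JSON config file; keyword overrides win."""
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def build_population(self) -> Population:
        if self.fixture is not None:
            return make_fixture_population(self.fixture, cv=self.cv)
        return make_uniform_population(
            self.criterion,
            self.n_cells,
            boundary_factor=self.boundary_factor,
            cv=self.cv,
        )

    def build_grid(self, pop: Population) -> TimeGrid:
        step = self.grid_step if self.grid_step is not None else self.criterion / 1000.0
        return TimeGrid(start=0.0, stop=float(pop.boundary), step=step)

    def learning_config(self) -> LearningConfig:
        return LearningConfig(
            criterion=self.criterion, epsilon=self.epsilon, n_trials=self.n_trials
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("timecellmap")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def _write_manifest(out_dir: Path, spec: SimulationSpec, command: str) -> None:
    manifest = {
        "command": command,
        "parameters": spec.to_dict(),
        "package_version": _package_version(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def run_simulate(spec: SimulationSpec, out_dir: str | Path) -> WidthReport:
    """Train a population and write weights CSV, field CSV and width JSON.

    Outputs (all deterministic for a given spec): ``weights.csv`` with the
    full per-trial trajectory, ``field.csv`` with the sampled average time
    field after the final trial, ``width_report.json``, and a
    ``manifest.json`` recording the parameters and package version.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pop = spec.build_population()
    trained, history = train(pop, spec.learning_config())
    field = average_time_field(trained, spec.build_grid(trained))
    report = measure_width(field)
    logger.info(
        "field peak %.3f s (criterion %.3f s)", report.peak_time, spec.criterion
    )
    history.to_csv(out_dir / "weights.csv", index=False)
    field.to_csv(out_dir / "field.csv")
    with open(out_dir / "width_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
    _write_manifest(out_dir, spec, "simulate")
    return report


def run_scalar(
    criteria: Sequence[float],
    out_dir: str | Path,
    spec: SimulationSpec | None = None,
    scale_epsilon: bool = False,
) -> pd.DataFrame:
    """Scalar-property analysis across criteria; writes CSV + JSON reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = spec if spec is not None else SimulationSpec(criterion=criteria[0])
    df = scalar_report(
        criteria,
        n_cells=base.n_cells,
        boundary_factor=base.boundary_factor,
        cv=base.cv,
        epsilon=base.epsilon,
        n_trials=base.n_trials,
        scale_epsilon=scale_epsilon,
    )
    df.to_csv(out_dir / "scalar_report.csv", index=False)
    with open(out_dir / "scalar_report.json", "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=2)
        fh.write("\n")
    _write_manifest(out_dir, base, "scalar")
    return df


def run_lesion(spec: SimulationSpec, out_dir: str | Path) -> dict:
    """Train, lesion, and report the signed peak shift (post - pre).

    Dorsal lesions remove the long-duration cells and shift the field peak
    leftward (negative shift); ventral lesions shift it rightward.
    """
    if spec.lesion_side is None:
        raise InvalidConfigError("lesion run requires lesion_side")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pop = spec.build_population()
    trained, _ = train(pop, spec.learning_config())
    pre = measure_width(average_time_field(trained, spec.build_grid(trained)))
    lesioned = lesion(trained, spec.lesion_side, spec.lesion_fraction)
    if len(lesioned) == 0:
        raise EmptyPopulationError("lesion removed every cell; no field to analyse")
    post = measure_width(average_time_field(lesioned, spec.build_grid(lesioned)))
    result = {
        "pre_lesion": pre.to_dict(),
        "post_lesion": post.to_dict(),
        "peak_shift_s": post.peak_time - pre.peak_time,
        "n_cells_removed": len(pop) - len(lesioned),
    }
    with open(out_dir / "lesion_report.json", "w") as fh:
        json.dump(result, fh, indent=2)
        fh.write("\n")
    _write_manifest(out_dir, spec, "lesion")
    return result
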