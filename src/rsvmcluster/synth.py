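"""Synthetic two-group cohorts with planted connectivity differences.

The generator emulates the structure of a two-group resting-state
study: every subject's regional time series is drawn from a zero-mean
multivariate normal whose correlation matrix is a shared modular
background — high correlation within functional modules, low between
them, the hallmark community structure of real functional connectomes —
except that in the patient group a set of planted region pairs has its
correlation raised by an effect size delta.  Group differences in graph
metrics then emerge downstream through the same correlation ->
threshold -> metrics pipeline used on real data, so the simulation
exercises every stage rather than injecting effects into the features
directly.

Defaults mirror the study conditions the pipeline targets: 90 regions,
110 retained time points, 40 subjects per group, delta = 0.4 planted on
30 edges over a 9-module background (within-module correlation 0.45,
between-module 0.08).  Setting ``n_modules=1`` degenerates to a uniform
compound-symmetry background at the between-module level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import LabeledDataset
from .graph import ROITimeSeries
from .regions import default_region_ids

logger = logging.getLogger(__name__)

_PD_EPS = 1e-6


@dataclass
class SimulationSpec:
    """Parameters of the planted-effect cohort simulation.

    Both groups share a modular background correlation matrix:
    ``within_module_correlation`` inside each of the ``n_modules``
    contiguous region blocks, ``base_correlation`` between blocks.
    Group A (controls, label +1) uses that background unchanged; group
    B (patients, label -1) adds ``effect_size`` to the correlation of
    every planted edge.  ``noise_sd`` adds white measurement noise on
    top of the latent signal (0 keeps the planted correlations exact on
    average).
    """

    n_regions: int = 90
    n_timepoints: int = 110
    n_group_a: int = 40
    n_group_b: int = 40
    n_modules: int = 9
    base_correlation: float = 0.08
    within_module_correlation: float = 0.45
    n_planted_edges: int = 30
    effect_size: float = 0.4
    noise_sd: float = 0.0
    seed: int = 0
    planted_edges: list[tuple[int, int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_timepoints < 3:
            raise ValueError("need at least 2 regions and 3 time points")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        if not 1 <= self.n_modules <= self.n_regions:
            raise ValueError("n_modules must lie in [1, n_regions]")
        if self.n_modules == 1:
            self.within_module_correlation = self.base_correlation
        if not 0.0 <= self.base_correlation < 1.0:
            raise ValueError("base_correlation must lie in [0, 1)")
        if not 0.0 <= self.within_module_correlation < 1.0:
            raise ValueError("within_module_correlation must lie in [0, 1)")
        top = max(self.base_correlation, self.within_module_correlation)
        if not 0.0 <= top + self.effect_size < 1.0:
            raise ValueError(
                "background correlation + effect_size must lie in [0, 1)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.planted_edges is None:
            self.planted_edges = random_planted_edges(
                self.n_regions, self.n_planted_edges, self.seed
            )
        self.planted_edges = [tuple(sorted(e)) for e in self.planted_edges]
        if len(set(self.planted_edges)) != len(self.planted_edges):
            raise ValueError("planted edges must be distinct")
        for i, j in self.planted_edges:
            if not (0 <= i < j < self.n_regions):
                raise ValueError(f"planted edge ({i}, {j}) out of range")


def random_planted_edges(
    n_regions: int, n_edges: int, seed: int
) -> list[tuple[int, int]]:
    """Draw ``n_edges`` distinct region pairs uniformly at random."""
    n_pairs = n_regions * (n_regions - 1) // 2
    if n_edges > n_pairs:
        raise ValueError(f"cannot plant {n_edges} edges among {n_pairs} pairs")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_regions, k=1)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    return [(int(iu[0][k]), int(iu[1][k])) for k in chosen]


def nearest_positive_definite(corr: np.ndarray, eps: float = _PD_EPS) -> np.ndarray:
    """Eigenvalue-clipping repair of a symmetric matrix to a correlation.

    Eigenvalues below ``eps`` are clipped up, then the result is rescaled
    to unit diagonal.  The Frobenius norm of the change is logged.
    """
    w, v = np.linalg.eigh(corr)
    if w.min() >= eps:
        return corr
    repaired = (v * np.clip(w, eps, None)) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    delta = float(np.linalg.norm(repaired - corr, "fro"))
    logger.info(
        "planted covariance repaired to positive definite (Frobenius change %.3g)",
        delta,
    )
    return repaired


def module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous block assignment of regions to modules."""
    sizes = np.full(n_modules, n_regions // n_modules)
    sizes[: n_regions % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


def group_correlation_matrices(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """The (control, patient) population correlation matrices."""
    n = spec.n_regions
    mod = module_assignment(n, spec.n_modules)
    base = np.where(
        mod[:, None] == mod[None, :],
        spec.within_module_correlation,
        spec.base_correlation,
    ).astype(float)
    np.fill_diagonal(base, 1.0)
    bumped = base.copy()
    for i, j in spec.planted_edges:
        bumped[i, j] += spec.effect_size
        bumped[j, i] += spec.effect_size
    base = nearest_positive_definite(base)
    bumped = nearest_positive_definite(bumped)
    if np.linalg.eigvalsh(bumped).min() <= 0 or np.linalg.eigvalsh(base).min() <= 0:
        raise ValueError("planted covariance could not be repaired to positive definite")
    return base, bumped


@dataclass
class Cohort:
    """A simulated two-group cohort of regional time series."""

    series: list[ROITimeSeries]
    labels: np.ndarray  # +1 control (group A), -1 patient (group B)
    subject_ids: list[str]
    spec: SimulationSpec

    def labeled_dataset(self, X: np.ndarray) -> LabeledDataset:
        """Attach a feature matrix (rows in cohort order) to the labels."""
        return LabeledDataset(X, self.labels, list(self.subject_ids))


def generate_cohort(spec: SimulationSpec) -> Cohort:
    """Simulate all subjects' time series for one two-group cohort."""
    rng = np.random.default_rng(spec.seed)
    corr_a, corr_b = group_correlation_matrices(spec)
    chol_a = np.linalg.cholesky(corr_a)
    chol_b = np.linalg.cholesky(corr_b)
    region_ids = default_region_ids(spec.n_regions)
    series: list[ROITimeSeries] = []
    labels: list[int] = []
    subject_ids: list[str] = []
    for chol, n_sub, label, tag in [
        (chol_a, spec.n_group_a, 1, "con"),
        (chol_b, spec.n_group_b, -1, "pat"),
    ]:
        for k in range(n_sub):
            z = rng.standard_normal((spec.n_timepoints, spec.n_regions))
            x = z @ chol.T
            if spec.noise_sd > 0:
                x = x + spec.noise_sd * rng.standard_normal(x.shape)
            series.append(ROITimeSeries(x, list(region_ids)))
            labels.append(label)
            subject_ids.append(f"{tag}-{k + 1:03d}")
    return Cohort(
        series=series,
        labels=np.array(labels, dtype=int),
        subject_ids=subject_ids,
        spec=spec,
    )


def toy_graph_fixtures() -> dict[str, dict]:
    """Small named graphs with hand-computed metric tables.

    Each entry holds a binary adjacency matrix plus the expected degree,
    clustering, local-efficiency and (where small enough to tabulate)
    shortest-path values, for use as exact test fixtures.
    """
    triangle = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    star = np.zeros((5, 5), dtype=int)
    star[0, 1:] = star[1:, 0] = 1
    path4 = np.diag(np.ones(3, dtype=int), 1)
    path4 = path4 + path4.T
    complete5 = 1 - np.eye(5, dtype=int)
    disconnected = np.zeros((6, 6), dtype=int)
    disconnected[0, 1] = disconnected[1, 0] = 1  # one edge, four isolates

    return {
        "triangle": {
            "adjacency": triangle,
            "degree": np.array([2, 2, 2]),
            "clustering": np.array([1.0, 1.0, 1.0]),
            "local_efficiency": np.array([1.0, 1.0, 1.0]),
            "shortest_path": np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]]),
        },
        "star": {
            "adjacency": star,
            "degree": np.array([4, 1, 1, 1, 1]),
            "clustering": np.zeros(5),
            "local_efficiency": np.zeros(5),
        },
        "path4": {
            "adjacency": path4,
            "degree": np.array([1, 2, 2, 1]),
            "clustering": np.zeros(4),
            "shortest_path": np.array(
                [[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]]
            ),
        },
        "complete5": {
            "adjacency": complete5,
            "degree": np.full(5, 4),
            "clustering": np.ones(5),
            "local_efficiency": np.ones(5),
            "shortest_path": 1 - np.eye(5, dtype=int),
        },
        "disconnected": {
            "adjacency": disconnected,
            "degree": np.array([1, 1, 0, 0, 0, 0]),
            "clustering": np.zeros(6),
            "local_efficiency": np.zeros(6),
        },
    }
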