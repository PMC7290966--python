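"""Functional connectivity, the Mantel test, and best-fit temperature T*.

Empirical FC is the Pearson correlation matrix of region-averaged BOLD
time series; simulated FC is the Pearson correlation matrix of the spin
time series sampled from the Ising model. The two are compared with a
Mantel permutation test on the strictly-upper-triangle entries, and T*
is the simulation temperature whose (run-averaged) FC correlates best
with the empirical FC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .ising import CouplingMatrix, SimulationParams, simulate_at_temperature

__all__ = [
    "CorrelationMatrix",
    "MantelResult",
    "TStarResult",
    "pearson_correlation_matrix",
    "average_fc_over_runs",
    "mantel_test",
    "find_tstar",
    "tstar_from_fc_curve",
    "direct_sc_fc_correlation",
    "select_best_scan",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric unit-diagonal Pearson correlation matrix.

    Regions whose time series had zero variance cannot be correlated;
    their off-diagonal entries are set to 0 and their indices recorded in
    ``degenerate_mask`` rather than propagating NaN.
    """

    r: np.ndarray
    kind: str  # "empirical" | "simulated"
    degenerate_mask: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.nanmax(np.abs(r)) > 1 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")
        if self.kind not in ("empirical", "simulated"):
            raise ValueError(f"unknown kind {self.kind!r}")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "degenerate_mask", frozenset(self.degenerate_mask))

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    degenerate: bool = False


@dataclass(frozen=True)
class TStarResult:
    T_star: float
    temperatures: np.ndarray
    mantel_curve: np.ndarray  # Mantel r per temperature
    best_r: float


def pearson_correlation_matrix(series: np.ndarray, kind: str = "empirical") -> CorrelationMatrix:
    """Pairwise Pearson correlation of a time x regions matrix.

    Zero-variance columns are flagged as degenerate: their off-diagonal
    correlations are set to 0 (the diagonal stays 1).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be a 2-D time x regions matrix")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = x.shape[1]
    sd = x.std(axis=0)
    # constant columns can carry O(eps) rounding noise; use a relative floor
    tiny = 1e-10 * np.maximum(1.0, np.abs(x).max(axis=0))
    degenerate = np.flatnonzero(sd <= tiny)
    ok = np.flatnonzero(sd > tiny)
    r = np.zeros((n, n))
    if ok.size >= 2:
        r[np.ix_(ok, ok)] = np.corrcoef(x[:, ok], rowvar=False)
    elif ok.size == 1:
        r[ok[0], ok[0]] = 1.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, kind=kind, degenerate_mask=frozenset(int(i) for i in degenerate))


def average_fc_over_runs(fcs: list[CorrelationMatrix]) -> CorrelationMatrix:
    """Entrywise mean of correlation matrices; diagonal reset to 1.

    Degenerate region flags are unioned across runs.
    """
    if not fcs:
        raise ValueError("cannot average an empty list of FC matrices")
    n = fcs[0].n_regions
    kind = fcs[0].kind
    mask: set[int] = set()
    acc = np.zeros((n, n))
    for fc in fcs:
        if fc.n_regions != n:
            raise ValueError("FC matrices must share the same region count")
        if fc.kind != kind:
            raise ValueError("FC matrices must share the same kind")
        acc += fc.r
        mask |= set(fc.degenerate_mask)
    acc /= len(fcs)
    np.fill_diagonal(acc, 1.0)
    return CorrelationMatrix(r=acc, kind=kind, degenerate_mask=frozenset(mask))


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _pearson_vec(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson r of two vectors; None if either is constant."""
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def mantel_r(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation of strictly-upper-triangle entries (0 if constant)."""
    r = _pearson_vec(_upper(A), _upper(B))
    return 0.0 if r is None else r


def mantel_test(
    A: CorrelationMatrix | np.ndarray,
    B: CorrelationMatrix | np.ndarray,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> MantelResult:
    """One-tailed (greater) Mantel permutation test.

    The observed statistic is the Pearson correlation of the two
    strictly-upper-triangle vectors. The null distribution is built by
    applying the same random node relabelling to the rows and columns of
    B; the p-value is (#{r_perm >= r_obs} + 1) / (n_permutations + 1).
    A constant upper triangle in either matrix yields the degenerate
    result r=0, p=1.
    """
    a = A.r if isinstance(A, CorrelationMatrix) else np.asarray(A, dtype=float)
    b = B.r if isinstance(B, CorrelationMatrix) else np.asarray(B, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 nodes")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    av, bv = _upper(a), _upper(b)
    if av.std() == 0 or bv.std() == 0:
        return MantelResult(r=0.0, p=1.0, n_permutations=n_permutations, degenerate=True)
    r_obs = float(np.corrcoef(av, bv)[0, 1])
    # centre/scale the fixed triangle once
    az = (av - av.mean()) / av.std()
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        bp = _upper(b[np.ix_(perm, perm)])
        s = bp.std()
        r_perm = 0.0 if s == 0 else float(az @ ((bp - bp.mean()) / s)) / av.size
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p=float(p), n_permutations=n_permutations)


def simulated_fc_at(
    coupling: CouplingMatrix,
    T: float,
    params: SimulationParams,
    n_runs: int,
    master_seed: int,
    seed_context: tuple = (),
) -> CorrelationMatrix:
    """Run-averaged simulated FC at one temperature (fresh random starts)."""
    fcs = []
    for run in range(n_runs):
        sub = derive_seed(master_seed, *seed_context, "fc", float(T), run)
        p = SimulationParams(
            temperature=float(T),
            n_equil_sweeps=params.n_equil_sweeps,
            n_samples=params.n_samples,
            sample_interval_sweeps=params.sample_interval_sweeps,
            seed=sub,
        )
        trace = simulate_at_temperature(coupling, p)
        fcs.append(pearson_correlation_matrix(trace.samples.astype(float), kind="simulated"))
    return average_fc_over_runs(fcs)


def tstar_from_fc_curve(
    sim_fcs: list[CorrelationMatrix],
    empirical: CorrelationMatrix,
    grid: np.ndarray,
) -> TStarResult:
    """Locate T* given precomputed per-temperature simulated FCs.

    T* is the grid temperature whose simulated FC has the highest Mantel
    r against the empirical FC; ties break toward the lowest temperature.
    """
    grid = np.asarray(grid, dtype=float)
    if len(sim_fcs) != grid.shape[0]:
        raise ValueError("need one simulated FC per grid temperature")
    curve = np.array([mantel_r(fc.r, empirical.r) for fc in sim_fcs])
    idx = int(np.argmax(curve))
    return TStarResult(
        T_star=float(grid[idx]),
        temperatures=grid,
        mantel_curve=curve,
        best_r=float(curve[idx]),
    )


def find_tstar(
    coupling: CouplingMatrix,
    empirical: CorrelationMatrix,
    grid: np.ndarray,
    params: SimulationParams,
    n_runs: int = 10,
    master_seed: int | None = None,
    seed_context: tuple = (),
) -> TStarResult:
    """Simulate across the grid and find the best-fit temperature T*."""
    if master_seed is None:
        master_seed = params.seed
    grid = np.asarray(grid, dtype=float)
    sim_fcs = [
        simulated_fc_at(coupling, T, params, n_runs, master_seed, seed_context)
        for T in grid
    ]
    return tstar_from_fc_curve(sim_fcs, empirical, grid)


def direct_sc_fc_correlation(coupling: CouplingMatrix, fc: CorrelationMatrix) -> float:
    """Pearson correlation between upper triangles of J and empirical FC.

    This is the no-model baseline the Ising simulation is meant to beat;
    a constant triangle in either matrix yields 0.
    """
    if coupling.n_regions != fc.n_regions:
        raise ValueError("coupling and FC must share the same region count")
    r = _pearson_vec(_upper(coupling.J), _upper(fc.r))
    return 0.0 if r is None else r


def select_best_scan(per_scan: dict[str, TStarResult]) -> str:
    """Scan label with the highest best_r; ties break toward 't1' (lowest label)."""
    if not per_scan:
        raise ValueError("no scans to select from")
    return min(per_scan, key=lambda lab: (-per_scan[lab].best_r, lab))
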