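"""Generalized Ising model on a weighted coupling matrix.

The model places one binary spin s_i in {+1, -1} on each brain region and
couples region pairs through the (normalized) structural connectome J_ij.
In the absence of an external field the energy of a configuration is the
full double sum

    E(s) = - sum_{i,j} J_ij s_i s_j

(each unordered pair contributes twice; the diagonal is zero). The system
is equilibrated against a thermal bath of dimensionless temperature T
(k_B = 1) with single-spin-flip Metropolis dynamics, and the sampled spin
configurations play the role of regional activity time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._kernels import run_chain

__all__ = [
    "CouplingMatrix",
    "SimulationParams",
    "SpinTrace",
    "normalize_coupling",
    "total_energy",
    "delta_energy",
    "metropolis_sweep",
    "simulate_at_temperature",
    "susceptibility",
]

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class CouplingMatrix:
    """Symmetric non-negative coupling matrix with zero diagonal.

    Parameters
    ----------
    J
        N x N symmetric matrix of non-negative couplings (dimensionless).
    normalization
        ``"raw"`` for untouched weights (e.g. streamline counts) or
        ``"max_one"`` when the maximum entry has been scaled to 1.
    """

    J: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        J = np.asarray(self.J, dtype=float)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError(f"coupling matrix must be square, got {J.shape}")
        if J.shape[0] < 2:
            raise ValueError("coupling matrix needs at least 2 regions")
        if not np.all(np.isfinite(J)):
            raise ValueError("coupling matrix contains non-finite entries")
        if np.any(J < 0):
            raise ValueError("coupling matrix contains negative entries")
        if np.abs(J - J.T).max() > _SYM_TOL:
            raise ValueError("coupling matrix is not symmetric")
        if np.any(np.diag(J) != 0):
            raise ValueError("coupling matrix has nonzero diagonal")
        if self.normalization not in ("raw", "max_one"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if J.max() == 0:
            raise ValueError("coupling matrix is all-zero")
        if self.normalization == "max_one" and not np.isclose(J.max(), 1.0):
            raise ValueError("max_one normalization requires max entry == 1")
        object.__setattr__(self, "J", J)

    @property
    def n_regions(self) -> int:
        return self.J.shape[0]


@dataclass(frozen=True)
class SimulationParams:
    """Monte Carlo settings for one temperature.

    ``n_equil_sweeps`` sweeps are discarded, then ``n_samples``
    configurations are recorded every ``sample_interval_sweeps`` sweeps.
    One sweep proposes N single-spin flips at uniformly random sites.
    """

    temperature: float
    n_equil_sweeps: int = 1000
    n_samples: int = 1000
    sample_interval_sweeps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.n_equil_sweeps < 0:
            raise ValueError("n_equil_sweeps must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.sample_interval_sweeps < 1:
            raise ValueError("sample_interval_sweeps must be >= 1")


@dataclass(frozen=True)
class SpinTrace:
    """Sampled spin configurations at one temperature."""

    samples: np.ndarray  # n_samples x N, int8 entries in {-1, +1}
    magnetization: np.ndarray  # per-sample mean spin
    energy: np.ndarray  # per-sample total energy (double-sum convention)
    params: SimulationParams

    @property
    def n_regions(self) -> int:
        return self.samples.shape[1]


def normalize_coupling(raw_counts: np.ndarray, symmetrize_tol: float = _SYM_TOL) -> CouplingMatrix:
    """Normalize a raw streamline-count matrix to a max-one coupling matrix.

    Zeroes the diagonal (self-coupling is meaningless), averages away
    asymmetry within ``symmetrize_tol`` of the matrix scale, and divides by
    the maximum entry so every subject's couplings share the scale
    max J = 1 and temperatures are comparable across subjects.
    """
    J = np.asarray(raw_counts, dtype=float).copy()
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"expected a square matrix, got {J.shape}")
    if not np.all(np.isfinite(J)):
        raise ValueError("matrix contains non-finite entries")
    if np.any(J < 0):
        raise ValueError("matrix contains negative entries")
    scale = max(np.abs(J).max(), 1.0)
    if np.abs(J - J.T).max() > symmetrize_tol * scale:
        raise ValueError("matrix asymmetry exceeds tolerance")
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    top = J.max()
    if top == 0:
        raise ValueError("matrix has no positive off-diagonal entry")
    return CouplingMatrix(J / top, normalization="max_one")


def _as_spins(s: np.ndarray, n: int) -> np.ndarray:
    s = np.asarray(s)
    if s.shape != (n,):
        raise ValueError(f"spin configuration must have shape ({n},), got {s.shape}")
    if not np.all(np.abs(s) == 1):
        raise ValueError("spins must be exactly +1 or -1")
    return s.astype(np.float64)


def total_energy(coupling: CouplingMatrix, s: np.ndarray) -> float:
    """E = -sum_{i,j} J_ij s_i s_j over the full double index range."""
    spins = _as_spins(s, coupling.n_regions)
    return float(-spins @ coupling.J @ spins)


def delta_energy(coupling: CouplingMatrix, s: np.ndarray, k: int) -> float:
    """Energy change of flipping spin k: 4 s_k sum_j J_kj s_j."""
    spins = _as_spins(s, coupling.n_regions)
    if not 0 <= k < coupling.n_regions:
        raise IndexError(f"spin index {k} out of range for N={coupling.n_regions}")
    return float(4.0 * spins[k] * (coupling.J[k] @ spins))


def _csr(coupling: CouplingMatrix):
    m = sp.csr_matrix(coupling.J)
    return m.indptr.astype(np.int64), m.indices.astype(np.int64), m.data.astype(np.float64)


def _run(coupling, s0, T, n_equil, n_samples, interval, rng):
    n = coupling.n_regions
    indptr, indices, weights = _csr(coupling)
    s = s0.astype(np.float64).copy()
    local = coupling.J @ s
    n_props = (n_equil + n_samples * interval) * n
    sites = rng.integers(0, n, size=n_props)
    logu = np.log(rng.random(size=n_props))
    samples = np.empty((n_samples, n), dtype=np.int8)
    m_out = np.empty(n_samples)
    e_out = np.empty(n_samples)
    run_chain(
        indptr, indices, weights, s, local, float(T),
        int(n_equil), int(n_samples), int(interval),
        sites, logu, samples, m_out, e_out,
    )
    return s, samples, m_out, e_out


def metropolis_sweep(
    coupling: CouplingMatrix,
    s: np.ndarray,
    T: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Metropolis sweep: N proposed flips at uniformly random sites.

    Each proposal is accepted with probability min(1, exp(-dE/T)).
    Returns the updated configuration as an int8 vector; the input is not
    mutated.
    """
    if not T > 0:
        raise ValueError("temperature must be positive")
    spins = _as_spins(s, coupling.n_regions)
    return _single_sweep(coupling, spins, T, rng)


def _single_sweep(coupling, spins, T, rng):
    indptr, indices, weights = _csr(coupling)
    n = coupling.n_regions
    s = spins.copy()
    local = coupling.J @ s
    sites = rng.integers(0, n, size=n)
    logu = np.log(rng.random(size=n))
    samples = np.empty((1, n), dtype=np.int8)
    m_out = np.empty(1)
    e_out = np.empty(1)
    run_chain(indptr, indices, weights, s, local, float(T), 0, 1, 1,
              sites, logu, samples, m_out, e_out)
    return samples[0].copy()


def random_spins(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random +-1 configuration of length n."""
    return (rng.integers(0, 2, size=n) * 2 - 1).astype(np.int8)


def simulate_at_temperature(
    coupling: CouplingMatrix,
    params: SimulationParams,
    initial: np.ndarray | str = "random",
) -> SpinTrace:
    """Equilibrate and sample the model at one temperature.

    Starts from ``initial`` (or a seed-determined random configuration),
    discards ``n_equil_sweeps`` sweeps, then records ``n_samples``
    configurations every ``sample_interval_sweeps`` sweeps together with
    their magnetization and energy. Identical (coupling, params) give a
    bit-identical trace.
    """
    rng = np.random.default_rng(params.seed)
    if isinstance(initial, str):
        if initial != "random":
            raise ValueError(f"unknown initial condition {initial!r}")
        s0 = random_spins(coupling.n_regions, rng).astype(np.float64)
    else:
        s0 = _as_spins(initial, coupling.n_regions)
    _, samples, m_out, e_out = _run(
        coupling, s0, params.temperature,
        params.n_equil_sweeps, params.n_samples, params.sample_interval_sweeps,
        rng,
    )
    return SpinTrace(samples=samples, magnetization=m_out, energy=e_out, params=params)


def susceptibility(trace: SpinTrace, use_abs: bool = True) -> float:
    """Magnetic susceptibility chi = N (<m^2> - <|m|>^2) / T.

    The |m| convention suppresses the spurious variance contributed by
    global-flip tunnelling between +-m in finite systems below the
    critical temperature; ``use_abs=False`` gives the raw-<m> estimator.
    """
    if trace.magnetization.shape[0] < 2:
        raise ValueError("susceptibility needs at least 2 samples")
    m = trace.magnetization
    center = np.abs(m).mean() if use_abs else m.mean()
    chi = trace.n_regions * (np.mean(m**2) - center**2) / trace.params.temperature
    return float(max(chi, 0.0))
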