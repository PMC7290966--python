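"""Connectome-distance dimensionality of functional correlations.

Distance between two regions is defined from connection strength, not
physical separation: strongly connected regions are close. With the
coupling matrix max-normalized, the reciprocal map d_ij = 1 / J_ij puts
the strongest pair at distance 1 and weakly connected pairs far apart
(zero-coupling pairs are excluded as unreachable at this order).

Functional correlation is then binned against this distance and the decay
is fit as a power law c(d) ~ d^(-gamma) on log-log axes. The decay
exponent maps to a dimensionality D = gamma + 2 - eta, so that zero decay
corresponds to a two-dimensional system and faster decay to higher
dimensionality (faster loss of information transfer with distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fc import CorrelationMatrix
from .ising import CouplingMatrix

__all__ = [
    "ConnectomeDistance",
    "DecayCurve",
    "DimensionalityEstimate",
    "coupling_to_distance",
    "correlation_decay_curve",
    "fit_dimensionality",
    "subject_dimensionality",
]

FC_SOURCES = ("simulated_at_Tc", "simulated_at_Tstar", "empirical")


@dataclass(frozen=True)
class ConnectomeDistance:
    """Pairwise connectome distance; unconnected pairs are excluded."""

    d: np.ndarray  # N x N, np.inf on excluded pairs and the diagonal
    n_excluded_pairs: int
    map: str  # "reciprocal" | "neglog"

    @property
    def n_regions(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class DecayCurve:
    bin_centers: np.ndarray  # ascending distances (geometric bin centres)
    mean_correlation: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centres must be strictly ascending")


@dataclass(frozen=True)
class DimensionalityEstimate:
    gamma: float  # decay exponent (slope magnitude of log c vs log d)
    D: float  # gamma + 2 - eta
    eta: float
    fit_r2: float
    n_bins_used: int
    fc_source: str = ""


def coupling_to_distance(coupling: CouplingMatrix, map: str = "reciprocal") -> ConnectomeDistance:
    """Distance from normalized coupling strength.

    ``reciprocal`` gives d = 1/J (minimum distance 1 at the strongest
    pair); ``neglog`` gives d = 1 - log(J) (also anchored at 1) for
    sensitivity analyses. Requires a max-one normalized coupling matrix
    so the anchor is well defined.
    """
    if coupling.normalization != "max_one":
        raise ValueError("distance is defined on a max-one normalized coupling matrix")
    J = coupling.J
    pos = J > 0
    d = np.full_like(J, np.inf)
    if map == "reciprocal":
        d[pos] = 1.0 / J[pos]
    elif map == "neglog":
        d[pos] = 1.0 - np.log(J[pos])
    else:
        raise ValueError(f"unknown distance map {map!r}")
    np.fill_diagonal(d, np.inf)
    n = J.shape[0]
    iu = np.triu_indices(n, k=1)
    n_excluded = int(np.sum(~pos[iu]))
    if n_excluded == iu[0].size:
        raise ValueError("no positive off-diagonal couplings: distance undefined")
    return ConnectomeDistance(d=d, n_excluded_pairs=n_excluded, map=map)


def correlation_decay_curve(
    fc: CorrelationMatrix,
    dist: ConnectomeDistance,
    n_bins: int = 12,
    min_pairs_per_bin: int = 3,
) -> DecayCurve:
    """Mean functional correlation in log-spaced connectome-distance bins.

    Pairs at infinite distance (no structural connection) are ignored.
    Bins holding fewer than ``min_pairs_per_bin`` pairs are dropped.
    """
    if fc.n_regions != dist.n_regions:
        raise ValueError("FC and distance matrices must share the same region count")
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if min_pairs_per_bin < 1:
        raise ValueError("min_pairs_per_bin must be >= 1")
    iu = np.triu_indices(fc.n_regions, k=1)
    d = dist.d[iu]
    c = fc.r[iu]
    finite = np.isfinite(d)
    d, c = d[finite], c[finite]
    if d.size == 0:
        raise ValueError("no connected pairs to bin")
    lo, hi = d.min(), d.max()
    if lo == hi:
        # all pairs at one distance: a single bin holding everything
        edges = np.array([lo * 0.999, lo * 1.001])
    else:
        edges = np.geomspace(lo, hi, n_bins + 1)
        edges[-1] *= 1 + 1e-12  # include the farthest pair
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, edges.size - 2)
    centers, means, counts = [], [], []
    for b in range(edges.size - 1):
        in_bin = idx == b
        n_pairs = int(in_bin.sum())
        if n_pairs < min_pairs_per_bin:
            continue
        centers.append(float(np.sqrt(edges[b] * edges[b + 1])))
        means.append(float(c[in_bin].mean()))
        counts.append(n_pairs)
    if not centers:
        raise ValueError("every distance bin is below min_pairs_per_bin")
    return DecayCurve(
        bin_centers=np.array(centers),
        mean_correlation=np.array(means),
        pair_counts=np.array(counts, dtype=int),
    )


def fit_dimensionality(curve: DecayCurve, eta: float = 0.0, fc_source: str = "") -> DimensionalityEstimate:
    """Power-law fit of the decay curve; D = gamma + 2 - eta.

    Ordinary least squares of log(mean correlation) on log(distance),
    using only bins with strictly positive mean correlation. gamma is the
    magnitude of the decay slope; a constant curve has gamma = 0 and is
    two-dimensional under the eta = 0 convention.
    """
    usable = curve.mean_correlation > 0
    x = np.log(curve.bin_centers[usable])
    y = np.log(curve.mean_correlation[usable])
    n_used = int(usable.sum())
    if n_used < 3:
        raise ValueError(
            f"power-law fit needs >= 3 bins with positive mean correlation, got {n_used}"
        )
    if np.ptp(x) == 0:
        raise ValueError("all usable bins share one distance; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    gamma = float(-slope)
    return DimensionalityEstimate(
        gamma=gamma,
        D=gamma + 2.0 - eta,
        eta=float(eta),
        fit_r2=r2,
        n_bins_used=n_used,
        fc_source=fc_source,
    )


def subject_dimensionality(
    coupling: CouplingMatrix,
    fc: CorrelationMatrix,
    fc_source: str,
    n_bins: int = 12,
    min_pairs_per_bin: int = 3,
    eta: float = 0.0,
    distance_map: str = "reciprocal",
) -> DimensionalityEstimate:
    """Distance -> decay curve -> power-law fit for one subject.

    ``fc_source`` records which FC was supplied (simulated_at_Tc,
    simulated_at_Tstar, or empirical) so estimates carry their provenance.
    """
    if fc_source not in FC_SOURCES:
        raise ValueError(f"fc_source must be one of {FC_SOURCES}")
    dist = coupling_to_distance(coupling, map=distance_map)
    curve = correlation_decay_curve(fc, dist, n_bins=n_bins, min_pairs_per_bin=min_pairs_per_bin)
    return fit_dimensionality(curve, eta=eta, fc_source=fc_source)
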