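"""Synthetic connectomes, lesions, BOLD-like scans, and full cohorts.

Since no subject MRI data ship with the analysis, this module generates
study-shaped stand-ins with known ground truth:

* geometric connectomes — regions placed uniformly in a unit cube whose
  pairwise weights fall off as a power of Euclidean distance, Poisson-
  rounded to integer pseudo-streamline counts (emulating tractography
  count matrices);
* lesioned variants — random edge deletion plus attenuation of the
  survivors, standing in for the diffuse white-matter damage of
  disorders-of-consciousness patients, with severity increasing along
  MCS+ -> MCS- -> VS/UWS;
* BOLD-like scans — spin time series simulated from the subject's own
  connectome near its critical temperature, plus Gaussian noise, so the
  empirical correlation structure is induced by the connectome as in
  real resting-state data;
* cohorts — 25 controls and 6/3/4 patients with two scans each,
  mirroring the study design, fully reproducible from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .criticality import mean_field_tc
from .io import BoldSeries, SubjectRecord
from .ising import CouplingMatrix, SimulationParams, normalize_coupling, simulate_at_temperature

__all__ = [
    "SyntheticCohortSpec",
    "lattice_connectome",
    "geometric_connectome",
    "lesion_connectome",
    "synth_bold",
    "synth_cohort",
]

DEFAULT_GROUP_SIZES = {"HC": 25, "VS_UWS": 6, "MCS_MINUS": 3, "MCS_PLUS": 4}
DEFAULT_LESION_FRACTIONS = {"HC": 0.0, "MCS_PLUS": 0.15, "MCS_MINUS": 0.30, "VS_UWS": 0.45}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-shaped synthetic cohort parameters.

    Defaults mirror the study design: 84 regions, 25 healthy controls,
    6 VS/UWS + 3 MCS- + 4 MCS+ patients, 480 time points per scan, two
    scans per subject. Lesion fractions increase with severity of the
    disorder; ``decay_alpha`` is the power-law exponent of connection
    weight versus embedding distance.
    """

    n_regions: int = 84
    n_per_group: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    embedding_dim: int = 3
    decay_alpha: float = 2.0
    lesion_fraction: dict = field(default_factory=lambda: dict(DEFAULT_LESION_FRACTIONS))
    lesion_attenuation: float = 0.8
    scan_length: int = 480
    noise_sigma: float = 0.2
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_per_group.values()):
            raise ValueError("group counts must be >= 0")
        f = self.lesion_fraction
        if any(not (0 <= v < 1) for v in f.values()):
            raise ValueError("lesion fractions must lie in [0, 1)")
        if not f["MCS_PLUS"] <= f["MCS_MINUS"] <= f["VS_UWS"]:
            raise ValueError("lesion fractions must be non-decreasing MCS+ -> MCS- -> VS/UWS")
        if not 0 < self.lesion_attenuation <= 1:
            raise ValueError("attenuation must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def lattice_connectome(side: int, periodic: bool = True) -> CouplingMatrix:
    """2-D nearest-neighbour lattice of side^2 nodes with unit couplings."""
    if side < 2:
        raise ValueError("side must be >= 2")
    n = side * side
    J = np.zeros((n, n))
    for i in range(side):
        for j in range(side):
            a = i * side + j
            for di, dj in ((0, 1), (1, 0)):
                ii, jj = i + di, j + dj
                if periodic:
                    ii %= side
                    jj %= side
                elif ii >= side or jj >= side:
                    continue
                b = ii * side + jj
                J[a, b] = J[b, a] = 1.0
    return CouplingMatrix(J, normalization="max_one")


def geometric_connectome(
    n: int,
    dim: int,
    alpha: float,
    rng: np.random.Generator,
    max_count: float = 1e4,
    integer_counts: bool = True,
) -> tuple[CouplingMatrix, np.ndarray]:
    """Distance-decay connectome from random points in the unit cube.

    Raw weight w_ij = (eps + ||x_i - x_j||)^(-alpha) with eps = 1e-3,
    scaled so the largest expected count is ``max_count`` and Poisson-
    rounded to integer pseudo-streamline counts (``integer_counts=False``
    keeps the noiseless continuous weights). Returns the max-one
    normalized coupling matrix and the ground-truth coordinates.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n < dim + 2:
        raise ValueError("need at least dim + 2 regions")
    x = rng.random((n, dim))
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    w = (1e-3 + d) ** (-alpha)
    np.fill_diagonal(w, 0.0)
    rates = np.triu(w, 1) * (max_count / w.max())
    if integer_counts:
        counts = rng.poisson(rates).astype(float)
    else:
        counts = rates
    counts = counts + counts.T
    return normalize_coupling(counts), x


def lesion_connectome(
    coupling: CouplingMatrix,
    edge_delete_fraction: float,
    attenuation: float,
    rng: np.random.Generator,
) -> CouplingMatrix:
    """Random diffuse damage: delete edges, attenuate survivors, renormalize.

    Each existing edge is independently deleted with probability
    ``edge_delete_fraction`` (both symmetric entries zeroed); surviving
    couplings are multiplied by ``attenuation`` and the result is
    renormalized to max-one.
    """
    if not 0 <= edge_delete_fraction <= 1:
        raise ValueError("edge_delete_fraction must lie in [0, 1]")
    if not 0 < attenuation <= 1:
        raise ValueError("attenuation must lie in (0, 1]")
    Ju = np.triu(coupling.J, 1)
    ii, jj = np.nonzero(Ju)
    keep = rng.random(ii.size) >= edge_delete_fraction
    if not np.any(keep):
        raise ValueError("lesion deleted every edge")
    out = np.zeros_like(Ju)
    out[ii[keep], jj[keep]] = Ju[ii[keep], jj[keep]] * attenuation
    return normalize_coupling(out + out.T)


def synth_bold(
    coupling: CouplingMatrix,
    T0: float,
    n_timepoints: int,
    noise_sigma: float,
    rng: np.random.Generator,
    scan_label: str = "t1",
    n_equil_sweeps: int = 1000,
    sample_interval_sweeps: int = 2,
) -> BoldSeries:
    """BOLD-like surrogate: spin dynamics at T0 plus Gaussian sensor noise.

    The spin time series sampled at temperature ``T0`` (ideally near the
    connectome's critical temperature, where correlation structure is
    richest) is perturbed with i.i.d. Gaussian noise of sd
    ``noise_sigma`` per entry.
    """
    if T0 <= 0:
        raise ValueError("T0 must be positive")
    seed = int(rng.integers(0, 2**31 - 1))
    params = SimulationParams(
        temperature=float(T0),
        n_equil_sweeps=n_equil_sweeps,
        n_samples=int(n_timepoints),
        sample_interval_sweeps=sample_interval_sweeps,
        seed=seed,
    )
    trace = simulate_at_temperature(coupling, params)
    values = trace.samples.astype(float)
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)
    return BoldSeries(values=values, scan_label=scan_label)


def synth_cohort(spec: SyntheticCohortSpec) -> tuple[list[SubjectRecord], dict]:
    """Generate a full synthetic cohort plus a ground-truth sidecar.

    Healthy controls get intact geometric connectomes; patient groups
    get lesioned variants with group-specific severity. Every subject
    receives two BOLD-like scans (labels t1/t2) simulated from their own
    connectome at its mean-field critical-temperature estimate, each
    with an independent derived sub-seed. The sidecar records every
    parameter and sub-seed needed to re-derive the cohort.
    """
    records: list[SubjectRecord] = []
    sidecar: dict = {
        "n_regions": spec.n_regions,
        "embedding_dim": spec.embedding_dim,
        "decay_alpha": spec.decay_alpha,
        "lesion_fraction": dict(spec.lesion_fraction),
        "lesion_attenuation": spec.lesion_attenuation,
        "scan_length": spec.scan_length,
        "noise_sigma": spec.noise_sigma,
        "master_seed": spec.master_seed,
        "subjects": {},
    }
    for group in ("HC", "VS_UWS", "MCS_MINUS", "MCS_PLUS"):
        for k in range(spec.n_per_group.get(group, 0)):
            sid = f"{group}{k + 1:02d}"
            conn_seed = derive_seed(spec.master_seed, "connectome", sid)
            rng = np.random.default_rng(conn_seed)
            coupling, coords = geometric_connectome(
                spec.n_regions, spec.embedding_dim, spec.decay_alpha, rng
            )
            frac = spec.lesion_fraction.get(group, 0.0)
            if frac > 0:
                lesion_seed = derive_seed(spec.master_seed, "lesion", sid)
                coupling = lesion_connectome(
                    coupling, frac, spec.lesion_attenuation, np.random.default_rng(lesion_seed)
                )
            T0 = mean_field_tc(coupling)
            scans = []
            scan_seeds = {}
            for label in ("t1", "t2"):
                sseed = derive_seed(spec.master_seed, "bold", sid, label)
                scan_seeds[label] = sseed
                scans.append(
                    synth_bold(
                        coupling,
                        T0,
                        spec.scan_length,
                        spec.noise_sigma,
                        np.random.default_rng(sseed),
                        scan_label=label,
                    )
                )
            records.append(
                SubjectRecord(
                    subject_id=sid, group=group, connectome=coupling, bold_scans=tuple(scans)
                )
            )
            sidecar["subjects"][sid] = {
                "group": group,
                "connectome_seed": conn_seed,
                "lesion_fraction": frac,
                "T0": T0,
                "scan_seeds": scan_seeds,
                "coordinates": coords.tolist(),
            }
    return records, sidecar
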