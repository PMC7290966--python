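"""Numba kernels for the Metropolis dynamics.

The coupling matrix is stored in CSR form (indptr/indices/weights) so that
sparse couplings (lattices, thresholded connectomes) update in O(degree)
while dense connectomes degrade gracefully to O(N). A running local-field
vector h_i = sum_j J_ij s_j makes the energy change of a proposed flip an
O(1) lookup; accepted flips push their contribution to the neighbours.

Energies follow the full double-sum convention E = -s^T J s (each unordered
pair contributes twice), so the energy change of flipping spin k is
4 s_k h_k.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(
    indptr,
    indices,
    weights,
    s,
    local,
    T,
    n_equil,
    n_samples,
    interval,
    sites,
    logu,
    samples_out,
    m_out,
    e_out,
):  # pragma: no cover - exercised through the python wrappers
    n = s.shape[0]
    total_sweeps = n_equil + n_samples * interval
    p = 0
    sample_idx = 0
    for sweep in range(total_sweeps):
        for _ in range(n):
            k = sites[p]
            d_e = 4.0 * s[k] * local[k]
            if d_e <= 0.0 or logu[p] < -d_e / T:
                s[k] = -s[k]
                push = 2.0 * s[k]
                for idx in range(indptr[k], indptr[k + 1]):
                    local[indices[idx]] += push * weights[idx]
            p += 1
        if sweep >= n_equil and (sweep - n_equil + 1) % interval == 0:
            m_acc = 0.0
            e_acc = 0.0
            for i in range(n):
                samples_out[sample_idx, i] = np.int8(s[i])
                m_acc += s[i]
                e_acc += s[i] * local[i]
            m_out[sample_idx] = m_acc / n
            e_out[sample_idx] = -e_acc
            sample_idx += 1
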