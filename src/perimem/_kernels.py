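"""Numba kernels for the hot loops: dilatation, bond forces, contact, breaking.

All kernels are single-threaded and loop over the CSR bond arrays of
:class:`~perimem.discretization.BondNetwork`; determinism of the accepted-step
sequence follows from fixed iteration order.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def compute_theta(y, indptr, indices, ref_len, intact, m, area, theta_out):
    """2D dilatation θ_i = (2/m_i) Σ_j ‖ξ‖ e A_j over intact bonds (ω ≡ 1)."""
    n = indptr.shape[0] - 1
    for i in range(n):
        acc = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            if not intact[k]:
                continue
            j = indices[k]
            dx = y[j, 0] - y[i, 0]
            dy = y[j, 1] - y[i, 1]
            cur = np.sqrt(dx * dx + dy * dy)
            acc += ref_len[k] * (cur - ref_len[k])
        if m[i] > 0.0:
            theta_out[i] = 2.0 * acc * area / m[i]
        else:
            theta_out[i] = 0.0


@njit(cache=True)
def compute_internal_force(y, indptr, indices, ref_len, intact, m, theta,
                           area, two_kappa, eight_g, force_out):
    """Assemble LPS force density: f_i = Σ_j (t_ij + t_ji) M_ij A_j.

    Scalar state t_ij = (2κ/m_i) θ_i ‖ξ‖ + (8G/m_i) e^d_ij with deviatoric
    extension e^d = e - θ‖ξ‖/2; direction M along the deformed bond.
    Coincident deformed positions of bonded particles contribute zero
    (contact machinery handles overlap); returns the count of such bonds.
    """
    n = indptr.shape[0] - 1
    degenerate = 0
    for i in range(n):
        fx = 0.0
        fy = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            if not intact[k]:
                continue
            j = indices[k]
            dx = y[j, 0] - y[i, 0]
            dy = y[j, 1] - y[i, 1]
            cur = np.sqrt(dx * dx + dy * dy)
            if cur <= 0.0:
                degenerate += 1
                continue
            r0 = ref_len[k]
            e = cur - r0
            ed_i = e - 0.5 * theta[i] * r0
            ed_j = e - 0.5 * theta[j] * r0
            t_pair = 0.0
            if m[i] > 0.0:
                t_pair += (two_kappa * theta[i] * r0 + eight_g * ed_i) / m[i]
            if m[j] > 0.0:
                t_pair += (two_kappa * theta[j] * r0 + eight_g * ed_j) / m[j]
            fx += t_pair * dx / cur
            fy += t_pair * dy / cur
        force_out[i, 0] = fx * area
        force_out[i, 1] = fy * area
    return degenerate


@njit(cache=True)
def compute_contact_force(y, pair_i, pair_j, pair_dpi, c_sr, area, force_out):
    """Short-range repulsion f = min{0, C_sr(‖y_j-y_i‖ - d_pi)}·unit vector.

    Applied pairwise (antisymmetric) over the cached proximity pair list.
    Exactly coincident particles repel along +x deterministically; returns
    the number of coincident pairs.
    """
    coincident = 0
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = y[j, 0] - y[i, 0]
        dy = y[j, 1] - y[i, 1]
        cur = np.sqrt(dx * dx + dy * dy)
        dpi = pair_dpi[p]
        if cur >= dpi:
            continue
        if cur <= 0.0:
            coincident += 1
            ux, uy = 1.0, 0.0
        else:
            ux, uy = dx / cur, dy / cur
        s = c_sr * (cur - dpi)  # negative: repulsive
        fx = s * ux * area
        fy = s * uy * area
        force_out[i, 0] += fx
        force_out[i, 1] += fy
        force_out[j, 0] -= fx
        force_out[j, 1] -= fy
    return coincident


@njit(cache=True)
def break_bonds(y, indptr, indices, ref_len, intact, reverse_index,
                critical_stretch, broken_count):
    """Break bonds with tensile stretch s = (‖y_j-y_i‖-‖ξ‖)/‖ξ‖ > s_c.

    Both directions of a pair break together; irreversible.  Returns the
    number of newly broken (undirected) bonds.
    """
    n = indptr.shape[0] - 1
    newly = 0
    for i in range(n):
        for k in range(indptr[i], indptr[i + 1]):
            if not intact[k]:
                continue
            j = indices[k]
            if j < i:
                continue  # visit each pair once
            dx = y[j, 0] - y[i, 0]
            dy = y[j, 1] - y[i, 1]
            cur = np.sqrt(dx * dx + dy * dy)
            r0 = ref_len[k]
            if (cur - r0) / r0 > critical_stretch:
                intact[k] = False
                intact[reverse_index[k]] = False
                broken_count[i] += 1
                broken_count[j] += 1
                newly += 1
    return newly


@njit(cache=True)
def max_displacement_since(y, y_ref):
    out = 0.0
    for i in range(y.shape[0]):
        dx = y[i, 0] - y_ref[i, 0]
        dy = y[i, 1] - y_ref[i, 1]
        d = np.sqrt(dx * dx + dy * dy)
        if d > out:
            out = d
    return out
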