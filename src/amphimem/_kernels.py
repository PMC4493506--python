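"""Numba-compiled inner loops: neighbor list build and force evaluation.

All kernels use orthorhombic periodic boundaries with the minimum-image
convention and accumulate the diagonal of the virial tensor so the caller
can form instantaneous (and lateral/normal) pressures.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["neighbor_pairs", "nonbonded_forces", "bond_forces", "angle_forces",
           "improper_forces"]


@njit(cache=True)
def _min_image(d, box):
    for a in range(3):
        d[a] -= box[a] * np.rint(d[a] / box[a])
    return d


@njit(cache=True)
def neighbor_pairs(pos, box, list_cutoff, excl):
    """All-pairs half neighbor list (i < j) within list_cutoff.

    ``excl`` is an (N, m) int64 array of excluded partner indices padded
    with -1 (directly bonded beads).
    """
    n = pos.shape[0]
    rc2 = list_cutoff * list_cutoff
    cap = max(64 * n, 1024)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                skip = False
                for e in range(excl.shape[1]):
                    if excl[i, e] == j:
                        skip = True
                        break
                    if excl[i, e] < 0:
                        break
                if skip:
                    continue
                if count >= cap:
                    newcap = cap * 2
                    npi = np.empty(newcap, dtype=np.int64)
                    npj = np.empty(newcap, dtype=np.int64)
                    npi[:count] = pi[:count]
                    npj[:count] = pj[:count]
                    pi = npi
                    pj = npj
                    cap = newcap
                pi[count] = i
                pj[count] = j
                count += 1
    return pi[:count].copy(), pj[:count].copy()


@njit(cache=True)
def nonbonded_forces(pos, box, pair_i, pair_j, tidx, eps_t, sig_t, q,
                     cutoff, a12, b12, c12s, a6, b6, c6s, r1_lj,
                     coul_pref, a1, b1, c1s, r1_c, forces, virial):
    """Shifted LJ + screened shifted Coulomb over a pair list.

    Returns (E_lj, E_coul, min_r2).  Forces and the virial diagonal are
    accumulated into the provided arrays.
    """
    e_lj = 0.0
    e_coul = 0.0
    min_r2 = 1.0e30
    rc2 = cutoff * cutoff
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < min_r2:
            min_r2 = r2
        if r2 >= rc2 or r2 <= 0.0:
            continue
        r = np.sqrt(r2)
        eps = eps_t[tidx[i], tidx[j]]
        sig = sig_t[tidx[i], tidx[j]]
        cc12 = 4.0 * eps * sig ** 12
        cc6 = 4.0 * eps * sig ** 6
        d = r - r1_lj
        if d < 0.0:
            d = 0.0
        inv = 1.0 / r
        inv2 = inv * inv
        inv6 = inv2 * inv2 * inv2
        inv12 = inv6 * inv6
        phi12 = inv12 - (a12 / 3.0) * d ** 3 - (b12 / 4.0) * d ** 4 - c12s
        f12 = 12.0 * inv12 * inv + a12 * d * d + b12 * d ** 3
        phi6 = inv6 - (a6 / 3.0) * d ** 3 - (b6 / 4.0) * d ** 4 - c6s
        f6 = 6.0 * inv6 * inv + a6 * d * d + b6 * d ** 3
        e_lj += cc12 * phi12 - cc6 * phi6
        fr = cc12 * f12 - cc6 * f6
        qq = q[i] * q[j]
        if qq != 0.0:
            cc1 = coul_pref * qq
            dc = r - r1_c
            if dc < 0.0:
                dc = 0.0
            phi1 = inv - (a1 / 3.0) * dc ** 3 - (b1 / 4.0) * dc ** 4 - c1s
            f1 = inv2 + a1 * dc * dc + b1 * dc ** 3
            e_coul += cc1 * phi1
            fr += cc1 * f1
        fs = fr * inv
        fx = fs * dx
        fy = fs * dy
        fz = fs * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz
    return e_lj, e_coul, min_r2


@njit(cache=True)
def bond_forces(pos, box, bi, bj, r0, k, forces, virial):
    e = 0.0
    for b in range(bi.shape[0]):
        i = bi[b]
        j = bj[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[b]
        e += 0.5 * k[b] * dr * dr
        fs = -k[b] * dr / r
        fx = fs * dx
        fy = fs * dy
        fz = fs * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz
    return e


@njit(cache=True)
def angle_forces(pos, box, ai, aj, ak, cos0, kang, forces, virial):
    """Cosine-harmonic angles U = 1/2 k (cos(theta) - cos0)^2 (regular at 180 deg)."""
    e = 0.0
    rij = np.empty(3)
    rkj = np.empty(3)
    for a in range(ai.shape[0]):
        i = ai[a]
        j = aj[a]
        kk = ak[a]
        for c in range(3):
            rij[c] = pos[i, c] - pos[j, c]
            rkj[c] = pos[kk, c] - pos[j, c]
        _min_image(rij, box)
        _min_image(rkj, box)
        lij = np.sqrt(rij[0] ** 2 + rij[1] ** 2 + rij[2] ** 2)
        lkj = np.sqrt(rkj[0] ** 2 + rkj[1] ** 2 + rkj[2] ** 2)
        dot = rij[0] * rkj[0] + rij[1] * rkj[1] + rij[2] * rkj[2]
        cosv = dot / (lij * lkj)
        if cosv > 1.0:
            cosv = 1.0
        elif cosv < -1.0:
            cosv = -1.0
        dc = cosv - cos0[a]
        e += 0.5 * kang[a] * dc * dc
        dudc = kang[a] * dc
        for c in range(3):
            dci = rkj[c] / (lij * lkj) - cosv * rij[c] / (lij * lij)
            dck = rij[c] / (lij * lkj) - cosv * rkj[c] / (lkj * lkj)
            fi = -dudc * dci
            fk = -dudc * dck
            forces[i, c] += fi
            forces[kk, c] += fk
            forces[j, c] -= fi + fk
            # virial from atom-based form relative to the vertex
            virial[c] += fi * rij[c] + fk * rkj[c]
    return e


@njit(cache=True)
def improper_forces(pos, box, di, dj, dk, dl, xi0, kimp, forces, virial):
    """Harmonic improper dihedrals U = 1/2 k (xi - xi0)^2 (ring planarity)."""
    e = 0.0
    b1 = np.empty(3)
    b2 = np.empty(3)
    b3 = np.empty(3)
    n1 = np.empty(3)
    n2 = np.empty(3)
    m = np.empty(3)
    for d in range(di.shape[0]):
        i = di[d]
        j = dj[d]
        k = dk[d]
        l = dl[d]
        for c in range(3):
            b1[c] = pos[j, c] - pos[i, c]
            b2[c] = pos[k, c] - pos[j, c]
            b3[c] = pos[l, c] - pos[k, c]
        _min_image(b1, box)
        _min_image(b2, box)
        _min_image(b3, box)
        n1[0] = b1[1] * b2[2] - b1[2] * b2[1]
        n1[1] = b1[2] * b2[0] - b1[0] * b2[2]
        n1[2] = b1[0] * b2[1] - b1[1] * b2[0]
        n2[0] = b2[1] * b3[2] - b2[2] * b3[1]
        n2[1] = b2[2] * b3[0] - b2[0] * b3[2]
        n2[2] = b2[0] * b3[1] - b2[1] * b3[0]
        lb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        m[0] = n1[1] * n2[2] - n1[2] * n2[1]
        m[1] = n1[2] * n2[0] - n1[0] * n2[2]
        m[2] = n1[0] * n2[1] - n1[1] * n2[0]
        y = (m[0] * b2[0] + m[1] * b2[1] + m[2] * b2[2]) / lb2
        x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        phi = np.arctan2(y, x)
        dphi = phi - xi0[d]
        # wrap into (-pi, pi]
        while dphi > np.pi:
            dphi -= 2.0 * np.pi
        while dphi <= -np.pi:
            dphi += 2.0 * np.pi
        e += 0.5 * kimp[d] * dphi * dphi
        dudphi = kimp[d] * dphi
        ln1s = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        ln2s = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        if ln1s < 1e-12 or ln2s < 1e-12:
            continue
        t = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (lb2 * lb2)
        s = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (lb2 * lb2)
        for c in range(3):
            fi = -dudphi * lb2 / ln1s * n1[c]
            fl = dudphi * lb2 / ln2s * n2[c]
            fj = -fi + t * fi - s * fl
            fk = -fl - t * fi + s * fl
            forces[i, c] += fi
            forces[j, c] += fj
            forces[k, c] += fk
            forces[l, c] += fl
            # virial relative to atom j (translation invariant)
            virial[c] += fi * (-b1[c]) + fk * b2[c] + fl * (b2[c] + b3[c])
    return e
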