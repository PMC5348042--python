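"""Independent Metropolis Monte Carlo oracle for the free spectrin chain.

Samples the chain's Boltzmann distribution directly (pivot + single-bead
moves) with the same Hamiltonian written out independently of the package:
harmonic bonds (k0 = 3.56 eps/sigma^2, rest 5 nm) plus the shifted, purely
repulsive 12-6 pair potential (eps/16, cutoff 5 nm) between all beads, at
kT = 0.03 eps.  Used to cross-check the molecular-dynamics sampling.
"""

import numpy as np
from numba import njit

SIG_NM = 4.45
EPS1_KT = 1.0 / (16.0 * 0.03)          # eps/16 in units of kT
K0_KT = 3.56 / 0.03 / SIG_NM**2        # bond constant in kT/nm^2
REQ_NM = 5.0
RCUT_NM = 5.0


@njit(cache=False)
def _energy(pos):
    n = pos.shape[0]
    e = 0.0
    for i in range(n - 1):
        d = np.sqrt(
            (pos[i, 0] - pos[i + 1, 0]) ** 2
            + (pos[i, 1] - pos[i + 1, 1]) ** 2
            + (pos[i, 2] - pos[i + 1, 2]) ** 2
        )
        e += 0.5 * K0_KT * (d - REQ_NM) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            r2 = (
                (pos[i, 0] - pos[j, 0]) ** 2
                + (pos[i, 1] - pos[j, 1]) ** 2
                + (pos[i, 2] - pos[j, 2]) ** 2
            )
            if r2 < RCUT_NM * RCUT_NM:
                s6 = (SIG_NM * SIG_NM / r2) ** 3
                e += 4.0 * EPS1_KT * (s6 * s6 - s6) + EPS1_KT
    return e


@njit(cache=False)
def run_chain_mc(n_beads, n_sweeps, burn_in, seed):
    """Return mean squared end-to-end distance (nm^2) from MC sampling."""
    np.random.seed(seed)
    pos = np.zeros((n_beads, 3))
    for i in range(n_beads):
        pos[i, 2] = i * REQ_NM
    e = _energy(pos)
    acc_ree2 = 0.0
    n_acc = 0
    for sweep in range(n_sweeps):
        # pivot moves
        for _ in range(4):
            k = 1 + np.random.randint(n_beads - 2)
            ax = np.random.standard_normal(3)
            ax /= np.sqrt(ax[0] ** 2 + ax[1] ** 2 + ax[2] ** 2)
            ang = (np.random.random() * 2.0 - 1.0) * np.pi
            c, s = np.cos(ang), np.sin(ang)
            new = pos.copy()
            for i in range(k + 1, n_beads):
                rx = pos[i, 0] - pos[k, 0]
                ry = pos[i, 1] - pos[k, 1]
                rz = pos[i, 2] - pos[k, 2]
                dot = ax[0] * rx + ax[1] * ry + ax[2] * rz
                cx = ax[1] * rz - ax[2] * ry
                cy = ax[2] * rx - ax[0] * rz
                cz = ax[0] * ry - ax[1] * rx
                new[i, 0] = pos[k, 0] + rx * c + cx * s + ax[0] * dot * (1 - c)
                new[i, 1] = pos[k, 1] + ry * c + cy * s + ax[1] * dot * (1 - c)
                new[i, 2] = pos[k, 2] + rz * c + cz * s + ax[2] * dot * (1 - c)
            en = _energy(new)
            if np.random.random() < np.exp(min(0.0, e - en)):
                pos, e = new, en
        # local displacement sweep
        for _ in range(n_beads):
            i = np.random.randint(n_beads)
            new = pos.copy()
            new[i, 0] += 0.3 * np.random.standard_normal()
            new[i, 1] += 0.3 * np.random.standard_normal()
            new[i, 2] += 0.3 * np.random.standard_normal()
            en = _energy(new)
            if np.random.random() < np.exp(min(0.0, e - en)):
                pos, e = new, en
        if sweep >= burn_in:
            acc_ree2 += (
                (pos[-1, 0] - pos[0, 0]) ** 2
                + (pos[-1, 1] - pos[0, 1]) ** 2
                + (pos[-1, 2] - pos[0, 2]) ** 2
            )
            n_acc += 1
    return acc_ree2 / n_acc
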