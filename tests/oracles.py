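"""Independent oracles used to cross-check the implementation.

Each routine here deliberately takes a different algorithmic route from the
package: exhaustive enumeration instead of dynamic programming, Horn's
quaternion eigenvector method instead of the SVD-based Kabsch fit, and a
dense all-pairs distance scan instead of the k-d tree search.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def enumerate_global_alignment_score(
    a: str,
    b: str,
    pair_score,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best global alignment score by exhaustive path enumeration.

    A gap run of length L costs gap_open + L*gap_extend. Feasible only for
    short sequences (the number of alignments grows as the Delannoy
    numbers); used for lengths <= 8.
    """
    best = -np.inf
    n, m = len(a), len(b)

    def rec(i: int, j: int, acc: float, prev: str) -> None:
        nonlocal best
        if i == n and j == m:
            if acc > best:
                best = acc
            return
        if i < n and j < m:
            rec(i + 1, j + 1, acc + pair_score(a[i], b[j]), "M")
        if i < n:
            cost = gap_extend + (gap_open if prev != "X" else 0.0)
            rec(i + 1, j, acc - cost, "X")
        if j < m:
            cost = gap_extend + (gap_open if prev != "Y" else 0.0)
            rec(i, j + 1, acc - cost, "Y")

    rec(0, 0, 0.0, "")
    return best


def quaternion_superposition_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Least-squares superposition RMSD via Horn's quaternion method.

    The optimal rotation is recovered from the largest eigenvalue of the
    4x4 key matrix built from the covariance of the centred point sets —
    no SVD involved.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    S = Qc.T @ Pc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    e2 = float(np.sum(Pc**2) + np.sum(Qc**2) - 2.0 * lam_max)
    return float(np.sqrt(max(e2, 0.0) / len(P)))


def all_pairs_min_distances(
    residue_coords: dict, ligand_coords: np.ndarray
) -> dict:
    """Minimum residue-to-ligand heavy-atom distance, dense O(N*M) scan."""
    return {
        key: float(cdist(np.asarray(coords), ligand_coords).min())
        for key, coords in residue_coords.items()
    }
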