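"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the optimal
superposition is computed by Horn's closed-form quaternion method instead
of SVD, and contact counting is a plain O(n²) double loop.
"""

import numpy as np


def horn_superpose(points_a: np.ndarray, points_b: np.ndarray):
    """Optimal rotation/translation of A onto B via the quaternion
    eigenvalue method; returns (rotation matrix, translation, rmsd)."""
    A = np.asarray(points_a, float)
    B = np.asarray(points_b, float)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    Sxx, Sxy, Sxz = (A0[:, 0] * B0[:, 0]).sum(), (A0[:, 0] * B0[:, 1]).sum(), (A0[:, 0] * B0[:, 2]).sum()
    Syx, Syy, Syz = (A0[:, 1] * B0[:, 0]).sum(), (A0[:, 1] * B0[:, 1]).sum(), (A0[:, 1] * B0[:, 2]).sum()
    Szx, Szy, Szz = (A0[:, 2] * B0[:, 0]).sum(), (A0[:, 2] * B0[:, 1]).sum(), (A0[:, 2] * B0[:, 2]).sum()
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    evals, evecs = np.linalg.eigh(K)
    w, x, y, z = evecs[:, np.argmax(evals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((A @ R.T + t - B) ** 2, axis=1))))
    return R, t, rmsd


def brute_force_counts(chains, contact_shell, clash_cutoff):
    """Inter-chain contact/clash counts by exhaustive pair enumeration."""
    contacts = clashes = 0
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            for p in chains[i]:
                for q in chains[j]:
                    d = float(np.linalg.norm(p - q))
                    if d <= contact_shell:
                        contacts += 1
                    if d <= clash_cutoff:
                        clashes += 1
    return contacts, clashes
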