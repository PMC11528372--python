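"""Shared structure-test helpers: synthetic Cα models, random rotations,
and the independent quaternion-method superposition oracle."""

import numpy as np

from rhodotools.structcmp import StructureModel


def random_rotation(rng):
    """Uniform random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def quaternion_superpose_rmsd(A, B):
    """Independent optimal-superposition RMSD via the quaternion method:
    the largest eigenvalue of the 4x4 key matrix built from the correlation
    matrix of the centered coordinates."""
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    M = B0.T @ A0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = np.sum(A0**2) + np.sum(B0**2)
    msd = max((e0 - 2.0 * lam) / len(A), 0.0)
    return float(np.sqrt(msd))


def helical_model(n=60, seed=0, chain="A"):
    """Idealized alpha-helical Cα trace (synthetic stand-in structure)."""
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    coords = np.column_stack(
        [2.3 * np.cos(i * 100 * np.pi / 180), 2.3 * np.sin(i * 100 * np.pi / 180),
         1.5 * i]
    )
    aas = "ACDEFGHIKLMNPQRSTVWY"
    seq = "".join(rng.choice(list(aas), n))
    return StructureModel(chain, list(range(1, n + 1)), seq, coords, source="synthetic")
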