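"""Balding-Nichols-style kinship from binary presence/absence markers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..covpav import PavMatrix

PSD_TOL = 1e-8


@dataclass
class KinshipMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        self.values = (v + v.T) / 2

    @property
    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def bn_kinship(matrix: PavMatrix) -> KinshipMatrix:
    """Frequency-standardized kinship from a 0/1 marker matrix.

    Monomorphic markers (frequency 0 or 1) carry no information and are
    excluded.  For marker k with presence frequency p_k the contribution
    to K(i, j) is (x_ik - p_k)(x_jk - p_k) / (p_k (1 - p_k)); K is the
    average over retained markers, which makes it symmetric and positive
    semidefinite up to rounding.
    """
    X = matrix.values().astype(float)  # markers x accessions
    p = X.mean(axis=1)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers: kinship undefined")
    Xp = X[poly]
    pp = p[poly][:, None]
    Z = (Xp - pp) / np.sqrt(pp * (1 - pp))
    K = Z.T @ Z / Z.shape[0]
    K = (K + K.T) / 2
    km = KinshipMatrix(ids=matrix.accessions, values=K)
    if km.min_eigenvalue < -PSD_TOL * max(1.0, float(np.abs(K).max())):
        raise AssertionError("kinship unexpectedly not PSD")
    return km
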