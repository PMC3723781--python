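"""Score functions: the pluggable ranking contract plus two concrete scorers.

The assembly loop ranks models by energy but does not care where the energy
comes from; anything satisfying the :class:`ScoreFunction` contract plugs
in.  Two scorers ship with the package:

* :class:`ReferenceScore` -- a native-blind coarse-grained potential (clash,
  compactness, local-contact terms) for honest prediction runs.
* :class:`OracleScore` -- a native-aware score equal to the CA RMSD to a
  hidden reference structure (plus optional per-model Gaussian noise).  It
  creates a perfectly funneled landscape and is the instrument used to
  validate that the distribution-estimation loop enriches near-native
  fragments when the energy is informative.

Energies are unitless; lower is better.  A score function must be
deterministic for a fixed conformation, which is why the optional noise of
the oracle lives in :meth:`ScoreFunction.record_energy` (called once per
finished model) rather than in ``__call__``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .conformation import Conformation, _as_ca

__all__ = ["ScoreFunction", "ReferenceScore", "OracleScore"]


@lru_cache(maxsize=32)
def _nonlocal_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=3)


def _sym3_singular_values(h: np.ndarray) -> tuple[float, float, float, float]:
    """Singular values of a 3x3 matrix plus sign(det), via the closed-form
    eigen decomposition of H^T H (trigonometric method)."""
    (h00, h01, h02), (h10, h11, h12), (h20, h21, h22) = h.tolist()
    det = (
        h00 * (h11 * h22 - h12 * h21)
        - h01 * (h10 * h22 - h12 * h20)
        + h02 * (h10 * h21 - h11 * h20)
    )
    # A = H^T H (symmetric PSD)
    a00 = h00 * h00 + h10 * h10 + h20 * h20
    a11 = h01 * h01 + h11 * h11 + h21 * h21
    a22 = h02 * h02 + h12 * h12 + h22 * h22
    a01 = h00 * h01 + h10 * h11 + h20 * h21
    a02 = h00 * h02 + h10 * h12 + h20 * h22
    a12 = h01 * h02 + h11 * h12 + h21 * h22
    q = (a00 + a11 + a22) / 3.0
    p2 = (a00 - q) ** 2 + (a11 - q) ** 2 + (a22 - q) ** 2 + 2.0 * (
        a01 * a01 + a02 * a02 + a12 * a12
    )
    p = math.sqrt(max(p2 / 6.0, 0.0))
    if p < 1e-14 * max(q, 1.0):
        s = math.sqrt(max(q, 0.0))
        return s, s, s, (1.0 if det >= 0 else -1.0)
    b00, b11, b22 = (a00 - q) / p, (a11 - q) / p, (a22 - q) / p
    b01, b02, b12 = a01 / p, a02 / p, a12 / p
    detb = (
        b00 * (b11 * b22 - b12 * b12)
        - b01 * (b01 * b22 - b12 * b02)
        + b02 * (b01 * b12 - b11 * b02)
    )
    r = min(max(detb / 2.0, -1.0), 1.0)
    phi = math.acos(r) / 3.0
    e1 = q + 2.0 * p * math.cos(phi)
    e3 = q + 2.0 * p * math.cos(phi + 2.0 * math.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    s1 = math.sqrt(max(e1, 0.0))
    s2 = math.sqrt(max(e2, 0.0))
    s3 = math.sqrt(max(e3, 0.0))
    return s1, s2, s3, (1.0 if det >= 0 else -1.0)


def superposed_rmsd_to(centered_ref: np.ndarray, ref_sq: float, ca: np.ndarray) -> float:
    """Kabsch RMSD of ``ca`` against a pre-centered reference (fast path)."""
    pc = ca - ca.mean(axis=0)
    p2 = float((pc * pc).sum())
    s1, s2, s3, sign = _sym3_singular_values(pc.T @ centered_ref)
    ssd = p2 + ref_sq - 2.0 * (s1 + s2 + sign * s3)
    return math.sqrt(max(ssd, 0.0) / len(ca))


class ScoreFunction:
    """Contract: map a conformation to a scalar energy, lower is better."""

    name: str = "abstract"

    def energy_from_coords(self, coords: np.ndarray) -> float:
        """Energy from an (n, 3, 3) backbone array (sampler fast path)."""
        raise NotImplementedError

    def __call__(self, conf: Conformation) -> float:
        return self.energy_from_coords(conf.coords)

    def record_energy(self, conf: Conformation, rng: np.random.Generator) -> float:
        """Energy recorded for a finished model; default is ``__call__``."""
        return self(conf)


@dataclass
class ReferenceScore(ScoreFunction):
    """Native-blind coarse-grained potential over CA positions.

    Terms (weighted sum):

    * soft-sphere clash: ``sum max(0, 4.0 - d_ij)^2`` over CA pairs at least
      3 residues apart;
    * radius of gyration: ``(Rg - 2.2 n^0.38)^2`` pulls toward globular
      compactness (the power law approximates folded-protein Rg scaling);
    * local-contact reward: minus the count of CA(i)-CA(i+3) distances in
      [4.5, 5.5] A, a proxy for helical/turn hydrogen bonding.
    """

    w_clash: float = 1.0
    w_rg: float = 1.0
    w_contact: float = 1.0
    clash_radius: float = 4.0
    name: str = "reference"

    def energy_from_ca(self, ca: np.ndarray) -> float:
        n = len(ca)
        diff = ca[:, None, :] - ca[None, :, :]
        d = np.sqrt((diff * diff).sum(axis=2))
        iu, ju = _nonlocal_pairs(n)
        gaps = self.clash_radius - d[iu, ju]
        clash = float((np.maximum(gaps, 0.0) ** 2).sum())
        centered = ca - ca.mean(axis=0)
        rg = np.sqrt((centered * centered).sum() / n)
        rg_term = float((rg - 2.2 * n**0.38) ** 2)
        d13 = d[np.arange(n - 3), np.arange(3, n)]
        contacts = float(((d13 >= 4.5) & (d13 <= 5.5)).sum())
        return (
            self.w_clash * clash + self.w_rg * rg_term - self.w_contact * contacts
        )

    def energy_from_coords(self, coords: np.ndarray) -> float:
        return self.energy_from_ca(coords[:, 1, :])


@dataclass
class OracleScore(ScoreFunction):
    """CA RMSD to a hidden native structure, optionally noised per model.

    ``__call__`` is the exact RMSD (deterministic).  ``record_energy`` adds
    one Normal(0, sigma) draw from the per-model random stream, emulating an
    imperfect but funneled energy function.
    """

    native_ca: np.ndarray = None  # (n, 3)
    sigma: float = 0.0
    name: str = "oracle"

    def __post_init__(self) -> None:
        self.native_ca = _as_ca(self.native_ca)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        self._centered = self.native_ca - self.native_ca.mean(axis=0)
        self._centered_sq = float((self._centered * self._centered).sum())

    def energy_from_ca(self, ca: np.ndarray) -> float:
        if len(ca) != len(self.native_ca):
            raise ValueError(
                f"conformation length {len(ca)} != native length "
                f"{len(self.native_ca)}"
            )
        return superposed_rmsd_to(self._centered, self._centered_sq, ca)

    def energy_from_coords(self, coords: np.ndarray) -> float:
        return self.energy_from_ca(coords[:, 1, :])

    def record_energy(self, conf: Conformation, rng: np.random.Generator) -> float:
        e = self(conf)
        if self.sigma > 0:
            e += float(rng.normal(0.0, self.sigma))
        return e
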