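"""General time-reversible (GTR) substitution model with optional discrete-gamma
rate variation.

The model is parameterised by stationary base frequencies ``pi`` (order
A, C, G, T), six symmetric exchangeabilities (order AC, AG, AT, CG, CT, GT;
GT is fixed to 1 for identifiability) and an optional gamma shape ``alpha``
with equal-probability rate categories (category means per Yang's discrete
approximation).  The rate matrix is normalised so that one unit of branch
length corresponds to one expected substitution per site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
#: integer codes for alignment characters; 4 encodes missing (N or gap)
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 4}
MISSING = 4

# index pairs for the six exchangeabilities, in order AC, AG, AT, CG, CT, GT
_EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability categories of Gamma(alpha, alpha).

    The category means sum-average to 1, so the expected overall rate is
    unchanged by rate variation.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k == 1:
        return np.ones(1)
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # mean of Gamma(a, a) on [lo, hi) times k: k * (I_{a+1}(a*hi) - I_{a+1}(a*lo))
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    upper[-1] = 1.0
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = k * (upper - lower)
    return rates


@dataclass
class SubstModel:
    """A reversible nucleotide substitution model.

    Parameters
    ----------
    pi : array-like of 4 floats
        Stationary base frequencies (A, C, G, T); must be positive and sum to 1.
    exch : array-like of 6 floats
        Symmetric exchangeabilities (AC, AG, AT, CG, CT, GT).
    gamma_shape : float, optional
        Shape of the discrete-gamma rate distribution; ``None`` disables
        among-site rate variation.
    n_rate_categories : int
        Number of discrete gamma categories (ignored when ``gamma_shape`` is
        ``None``).
    scale : float
        Overall rate multiplier applied on top of the unit normalisation.
    """

    pi: np.ndarray
    exch: np.ndarray
    gamma_shape: float | None = None
    n_rate_categories: int = 1
    scale: float = 1.0
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.exch = np.asarray(self.exch, dtype=float)
        if self.pi.shape != (4,) or np.any(self.pi <= 0):
            raise ValueError("pi must be 4 positive frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if self.exch.shape != (6,) or np.any(self.exch < 0):
            raise ValueError("exch must be 6 non-negative values")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def jukes_cantor(cls) -> "SubstModel":
        """Uniform frequencies and equal exchangeabilities (JC69-equivalent)."""
        return cls(pi=np.full(4, 0.25), exch=np.ones(6))

    @classmethod
    def gtr(
        cls,
        pi,
        exch,
        gamma_shape: float | None = None,
        n_rate_categories: int = 4,
    ) -> "SubstModel":
        return cls(
            pi=pi,
            exch=exch,
            gamma_shape=gamma_shape,
            n_rate_categories=n_rate_categories if gamma_shape else 1,
        )

    # -- rate matrix ----------------------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        """The 4x4 rate matrix Q, normalised to 1 expected substitution/site."""
        q = np.zeros((4, 4))
        for r, (i, j) in zip(self.exch, _EXCH_PAIRS):
            q[i, j] = r * self.pi[j]
            q[j, i] = r * self.pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.pi, np.diag(q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix (all exchangeabilities zero?)")
        return q / mu

    def _eigen(self):
        """Eigendecomposition of the symmetrised rate matrix (cached)."""
        if self._eig is None:
            q = self.rate_matrix()
            sq = np.sqrt(self.pi)
            sym = (q * sq[:, None]) / sq[None, :]
            w, v = np.linalg.eigh((sym + sym.T) / 2.0)
            left = v.T * sq[None, :]       # V^T D^{1/2}
            right = v / sq[:, None]        # D^{-1/2} V
            self._eig = (w, right, left)
        return self._eig

    def transition_matrices(self, branch_lengths) -> np.ndarray:
        """P(t) for an array of branch lengths, shape (len(t), 4, 4)."""
        t = np.atleast_1d(np.asarray(branch_lengths, dtype=float)) * self.scale
        if np.any(t < 0):
            raise ValueError("negative branch length")
        w, right, left = self._eigen()
        expwt = np.exp(np.outer(t, w))                      # (n, 4)
        p = np.einsum("ij,nj,jk->nik", right, expwt, left)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p

    def rate_category_multipliers(self) -> np.ndarray:
        """Per-category rate multipliers (length 1 without gamma)."""
        if self.gamma_shape is None or self.n_rate_categories <= 1:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "exch": self.exch.tolist(),
            "gamma_shape": self.gamma_shape,
            "n_rate_categories": self.n_rate_categories,
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubstModel":
        return cls(
            pi=np.asarray(d["pi"]),
            exch=np.asarray(d["exch"]),
            gamma_shape=d.get("gamma_shape"),
            n_rate_categories=d.get("n_rate_categories", 1),
            scale=d.get("scale", 1.0),
        )

    def to_json(self, path, tree_newick: str | None = None) -> None:
        d = self.to_dict()
        if tree_newick is not None:
            d["tree_newick"] = tree_newick
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> tuple["SubstModel", str | None]:
        with open(path) as fh:
            d = json.load(fh)
        return cls.from_dict(d), d.get("tree_newick")


def encode_sequences(seqs) -> np.ndarray:
    """Encode an iterable of equal-length strings as an int8 matrix of
    base codes, columns-by-taxa: result[c, i] is the code of sequence ``i``
    at column ``c``.  Characters outside {A,C,G,T,N,-} map to missing."""
    seqs = list(seqs)
    n = len(seqs[0])
    out = np.full((n, len(seqs)), MISSING, dtype=np.int8)
    lut = np.full(256, MISSING, dtype=np.int8)
    for ch, code in BASE_CODES.items():
        lut[ord(ch)] = code
        lut[ord(ch.lower())] = code
    for i, s in enumerate(seqs):
        if len(s) != n:
            raise ValueError("sequences must have equal length")
        out[:, i] = lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    return out


def decode_columns(columns: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`: per-taxon strings from codes."""
    alphabet = np.frombuffer(b"ACGTN", dtype=np.uint8)
    cols = np.asarray(columns)
    return [
        alphabet[cols[:, i]].tobytes().decode("ascii")
        for i in range(cols.shape[1])
    ]
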