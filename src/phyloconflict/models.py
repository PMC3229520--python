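"""Substitution models: GTR/JC for nucleotides, WAG for amino acids.

All models are time-reversible, normalized to one expected substitution
per site at stationarity, and carry a discrete-gamma-plus-invariant-sites
rate mixture (4 equal-probability categories with mean rates, the standard
discretization).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

NUC_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"  # PAML order

#: IUPAC nucleotide ambiguity codes -> compatible states.
NUC_AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT",
}


def _load_wag() -> tuple[np.ndarray, np.ndarray]:
    data = importlib.resources.files("phyloconflict.data")
    rates = np.loadtxt(str(data / "wag_exchangeabilities.txt"))
    freqs = np.loadtxt(str(data / "wag_frequencies.txt"))
    n = 20
    exch = np.zeros((n, n))
    # Column-major lower triangle (all pairs with state 1 first, etc.).
    k = 0
    for j in range(n):
        for i in range(j + 1, n):
            exch[i, j] = exch[j, i] = rates[k]
            k += 1
    return exch, freqs / freqs.sum()


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability gamma bins, normalized to 1.

    The gamma has shape ``alpha`` and mean 1. The mean of bin *i* bounded by
    quantiles (b_{i-1}, b_i) is ``ncat * (F_{a+1}(b_i) - F_{a+1}(b_{i-1}))``
    where F_{a+1} is the CDF of a Gamma(alpha+1) with the same rate.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    if ncat == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    upper = gammainc(alpha + 1, np.where(np.isinf(bounds), np.inf, bounds * alpha))
    upper[np.isinf(bounds)] = 1.0
    rates = ncat * np.diff(upper)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """A reversible substitution model with a +G+I rate mixture.

    Parameters
    ----------
    kind:
        ``"GTR"``, ``"JC"`` (nucleotides) or ``"WAG"`` (amino acids).
    exchangeabilities:
        Symmetric positive rates. For nucleotides, 6 values in the order
        AC, AG, AT, CG, CT, GT. Ignored for JC and WAG.
    frequencies:
        Stationary distribution (must sum to 1). Defaults: uniform for
        JC/GTR, empirical for WAG.
    alpha:
        Gamma shape; ``None`` disables rate heterogeneity (1 category).
    pinv:
        Proportion of invariant sites in [0, 1).
    """

    kind: str = "JC"
    exchangeabilities: Optional[np.ndarray] = None
    frequencies: Optional[np.ndarray] = None
    alpha: Optional[float] = None
    pinv: float = 0.0
    ncat: int = 4

    def __post_init__(self):
        kind = self.kind.upper()
        if kind not in {"GTR", "JC", "WAG"}:
            raise ValueError(f"unknown model kind: {self.kind}")
        self.kind = kind
        if kind == "WAG":
            exch, freqs = _load_wag()
            self.exchangeabilities = exch
            if self.frequencies is None:
                self.frequencies = freqs
        elif kind == "JC":
            self.exchangeabilities = np.ones((4, 4)) - np.eye(4)
            self.frequencies = np.full(4, 0.25)
        else:  # GTR
            if self.exchangeabilities is None:
                rates6 = np.ones(6)
            else:
                rates6 = np.asarray(self.exchangeabilities, dtype=float).ravel()
            if rates6.shape == (6,):
                exch = np.zeros((4, 4))
                idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
                for r, (i, j) in zip(rates6, idx):
                    exch[i, j] = exch[j, i] = r
                self.exchangeabilities = exch
            else:
                self.exchangeabilities = rates6.reshape(4, 4)
            if self.frequencies is None:
                self.frequencies = np.full(4, 0.25)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if abs(self.frequencies.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.asarray(self.exchangeabilities) < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if not (0.0 <= self.pinv <= 1.0):
            raise ValueError("pinv must be in [0, 1]")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        self._decompose()

    # -- derived quantities ------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.frequencies)

    @property
    def states(self) -> str:
        return AA_STATES if self.n_states == 20 else NUC_STATES

    @property
    def is_nucleotide(self) -> bool:
        return self.n_states == 4

    def rate_matrix(self) -> np.ndarray:
        """Normalized instantaneous rate matrix Q (1 subst/site/unit time)."""
        return self._Q

    def _decompose(self):
        pi = self.frequencies
        Q = np.asarray(self.exchangeabilities, dtype=float) * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q = Q / mu
        self._Q = Q
        # Reversible: symmetrize with sqrt(pi) and use a stable eigh.
        sp = np.sqrt(pi)
        B = (Q * sp[:, None]) / sp[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = eigval
        self._right = eigvec / sp[:, None]          # U = diag(1/sqrt(pi)) V
        self._left = eigvec.T * sp[None, :]         # U^-1 = V^T diag(sqrt(pi))

    def category_rates(self) -> np.ndarray:
        """Rates of the gamma categories (excluding the invariant class)."""
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.ncat)

    def mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """(weights, rates) of the full rate mixture including invariants.

        Gamma-category rates are divided by (1 - pinv) so the overall
        expected rate stays 1 substitution/site.
        """
        if self.pinv >= 1.0:  # degenerate: everything invariant
            return np.ones(1), np.zeros(1)
        grates = self.category_rates()
        gweights = np.full(len(grates), (1.0 - self.pinv) / len(grates))
        if self.pinv > 0:
            rates = np.concatenate([[0.0], grates / (1.0 - self.pinv)])
            weights = np.concatenate([[self.pinv], gweights])
        else:
            rates, weights = grates, gweights
        return weights, rates

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for branch length ``t`` in substitutions/site."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stack of P(t * r) for each mixture rate r, shape (k, n, n)."""
        if len(rates) == 1:
            P = ((self._right * np.exp(self._eigval * (t * rates[0]))[None, :])
                 @ self._left)[None]
            P = P.copy()
        else:
            scaled = np.exp(self._eigval[None, :] * (t * np.asarray(rates))[:, None])
            P = np.einsum("ij,kj,jl->kil", self._right, scaled, self._left)
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            "kind": self.kind,
            "alpha": self.alpha,
            "pinv": float(self.pinv),
            "ncat": int(self.ncat),
        }
        if self.kind == "GTR":
            exch = np.asarray(self.exchangeabilities)
            idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
            data["exchangeabilities"] = [float(exch[i, j]) for i, j in idx]
            data["frequencies"] = [float(f) for f in self.frequencies]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SubstitutionModel":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def leaf_partial(self, symbol: str) -> np.ndarray:
        """Partial-likelihood row for one observed symbol (ambiguity-aware)."""
        symbol = symbol.upper()
        n = self.n_states
        if self.is_nucleotide:
            allowed = NUC_AMBIGUITY.get(symbol)
            if allowed is None:
                raise ValueError(f"illegal nucleotide symbol {symbol!r}")
            vec = np.zeros(n)
            for s in allowed:
                vec[NUC_STATES.index(s)] = 1.0
            return vec
        if symbol in ("-", "?", ".", "X"):
            return np.ones(n)
        if symbol == "B":
            vec = np.zeros(n)
            vec[AA_STATES.index("N")] = vec[AA_STATES.index("D")] = 1.0
            return vec
        if symbol == "Z":
            vec = np.zeros(n)
            vec[AA_STATES.index("Q")] = vec[AA_STATES.index("E")] = 1.0
            return vec
        if symbol not in AA_STATES:
            raise ValueError(f"illegal amino acid symbol {symbol!r}")
        vec = np.zeros(n)
        vec[AA_STATES.index(symbol)] = 1.0
        return vec
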