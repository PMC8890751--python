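"""Reversible amino-acid substitution models.

A model couples one symmetric exchangeability matrix with one or more
stationary frequency profiles (a single profile gives an "LG+G4+F"-style
site-homogeneous model; several give a "C-series"-style profile mixture
with fixed weights) and discrete-gamma rate variation across sites.

Every profile's rate matrix is normalised to one expected substitution
per unit branch length, so branch lengths are in expected
substitutions/site under the slowest-to-fastest mixture average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import AMINO_ACIDS, Alignment

N_STATES = 20
#: PAML ordering used by the bundled LG data file
PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"


class ModelError(ValueError):
    pass


def build_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """GTR-style rate matrix: q_ij = s_ij * pi_j, normalised to rate 1.

    The diagonal is set for zero row sums and the whole matrix rescaled
    so the expected rate −Σ_i π_i q_ii equals 1 exactly.
    """
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if S.shape != (N_STATES, N_STATES):
        raise ModelError(f"S must be {N_STATES}x{N_STATES}")
    if not np.allclose(S, S.T, atol=1e-12):
        raise ModelError("exchangeability matrix must be symmetric")
    if np.any(S < 0) or np.any(np.diag(S) != 0):
        raise ModelError("S must be non-negative with zero diagonal")
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ModelError("pi must be a strictly positive simplex vector")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ModelError("degenerate rate matrix")
    return Q / mu


def _symmetric_eigen(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of the π-symmetrised generator.

    Returns (lam, U, sqp) with P(t) = diag(1/sqp) U diag(e^{lam t}) U' diag(sqp).
    """
    sqp = np.sqrt(pi)
    B = (Q * sqp[:, None]) / sqp[None, :]
    B = 0.5 * (B + B.T)  # kill round-off asymmetry
    lam, U = np.linalg.eigh(B)
    return lam, U, sqp


def transition_probs(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) for a reversible Q; rows sum to 1, entries in [0, 1]."""
    if t < 0:
        raise ModelError("negative branch length")
    if pi is None:
        # stationary dist of a normalised reversible Q: solve πQ = 0
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
    lam, U, sqp = _symmetric_eigen(Q, pi)
    P = (U * np.exp(lam * t)) @ U.T
    P = P * sqp[None, :] / sqp[:, None]
    return np.clip(P, 0.0, 1.0)


def gamma_category_rates(alpha: float, K: int) -> np.ndarray:
    """Mean-of-bin discrete-gamma rates, renormalised to mean exactly 1.

    Sites fall in K equiprobable bins of a Gamma(alpha, alpha) density
    (mean 1); each category's rate is the conditional mean within its
    bin.
    """
    if alpha <= 0 or K < 1:
        raise ModelError("alpha must be > 0 and K >= 1")
    if K == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(K + 1) / K, a=alpha, scale=1.0 / alpha)
    # E[X | bin] * (1/K)^{-1}: mass of Gamma(alpha+1, alpha) in each bin
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    upper[-1] = 1.0
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = K * (upper - lower)
    return rates / rates.mean()


def empirical_frequencies(alignment: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """Observed amino-acid frequencies with a pseudocount per state."""
    counts = np.full(N_STATES, pseudocount)
    for i, aa in enumerate(AMINO_ACIDS):
        counts[i] += (alignment.data == aa).sum()
    return counts / counts.sum()


def _floor_profile(pi: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    pi = np.maximum(np.asarray(pi, dtype=float), floor)
    return pi / pi.sum()


@dataclass
class SubstitutionModel:
    """Exchangeabilities + frequency profile(s) + discrete-gamma rates.

    ``profiles`` is a list of ``(pi, weight)`` pairs; weights must sum
    to 1.  A single profile is the site-homogeneous case.  Mixture class
    weights are fixed (loaded, not optimised), mirroring how C-series
    models are used in practice.
    """

    S: np.ndarray
    profiles: list[tuple[np.ndarray, float]]
    alpha: float = 1.0
    K: int = 4
    frequency_mode: str = "model"
    name: str = ""
    _eigen: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.profiles = [(_floor_profile(p), float(w)) for p, w in self.profiles]
        wsum = sum(w for _, w in self.profiles)
        if abs(wsum - 1.0) > 1e-8:
            raise ModelError(f"profile weights sum to {wsum}, expected 1")
        if self.alpha <= 0 or self.K < 1:
            raise ModelError("invalid gamma parameters")

    # -- cached spectral machinery -------------------------------------
    @property
    def n_profiles(self) -> int:
        return len(self.profiles)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.profiles])

    @property
    def freqs(self) -> np.ndarray:
        """(M, 20) stationary frequencies, one row per profile."""
        return np.array([p for p, _ in self.profiles])

    @property
    def rates(self) -> np.ndarray:
        return gamma_category_rates(self.alpha, self.K)

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return SubstitutionModel(self.S, [(p.copy(), w) for p, w in self.profiles],
                                 alpha=alpha, K=self.K,
                                 frequency_mode=self.frequency_mode, name=self.name)

    def eigen(self):
        if self._eigen is None:
            eig = []
            for pi, _ in self.profiles:
                Q = build_rate_matrix(self.S, pi)
                eig.append(_symmetric_eigen(Q, pi))
            self._eigen = eig
        return self._eigen

    def rate_matrix(self, m: int = 0) -> np.ndarray:
        return build_rate_matrix(self.S, self.profiles[m][0])

    def transition_matrices(self, t: float) -> np.ndarray:
        """All (M*K, 20, 20) transition matrices for branch length t.

        Component order is profile-major: (m, k) → m * K + k.
        """
        if t < 0:
            raise ModelError("negative branch length")
        rates = self.rates
        out = np.empty((self.n_profiles * self.K, N_STATES, N_STATES))
        for m, (lam, U, sqp) in enumerate(self.eigen()):
            for k, r in enumerate(rates):
                P = (U * np.exp(lam * r * t)) @ U.T
                out[m * self.K + k] = np.clip(P * sqp[None, :] / sqp[:, None], 0.0, 1.0)
        return out

    def n_free_parameters(self, n_leaves: int) -> int:
        """Free parameters for BIC: branch lengths + alpha (+19 if +F)."""
        k = (2 * n_leaves - 3) + 1
        if self.frequency_mode == "empirical":
            k += 19
        return k


def bic(ll: float, n_free_params: int, n_sites: int) -> float:
    """Bayesian information criterion: k·ln(n) − 2·ll (lower is better)."""
    if n_sites < 1:
        raise ModelError("n_sites must be >= 1")
    return n_free_params * np.log(n_sites) - 2.0 * ll


# ---------------------------------------------------------------------------
# bundled model data & profile files
# ---------------------------------------------------------------------------

def load_lg() -> tuple[np.ndarray, np.ndarray]:
    """LG exchangeabilities and stationary frequencies (alphabetical order).

    The bundled data file stores the published constants in PAML state
    order; both outputs are re-indexed to this package's alphabetical
    amino-acid ordering.
    """
    text = resources.files("vertmark.data").joinpath("lg.dat").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    S_paml = np.zeros((N_STATES, N_STATES))
    for i, ln in enumerate(lines[:19], start=1):
        vals = [float(x) for x in ln.split()]
        S_paml[i, :i] = vals
        S_paml[:i, i] = vals
    pi_paml = np.array([float(x) for x in lines[19].split()])
    idx = [PAML_ORDER.index(aa) for aa in AMINO_ACIDS]
    S = S_paml[np.ix_(idx, idx)]
    pi = pi_paml[idx] / pi_paml.sum()
    return S, pi


def lg_model(alpha: float = 1.0, K: int = 4,
             freqs: np.ndarray | str | None = None,
             alignment: Alignment | None = None) -> SubstitutionModel:
    """Site-homogeneous LG model (optionally +F from an alignment)."""
    S, pi_lg = load_lg()
    mode = "model"
    if isinstance(freqs, str) and freqs == "empirical":
        if alignment is None:
            raise ModelError("empirical frequencies need an alignment")
        pi, mode = empirical_frequencies(alignment), "empirical"
    elif freqs is not None:
        pi = np.asarray(freqs, dtype=float)
    else:
        pi = pi_lg
    name = f"LG+G{K}" + ("+F" if mode == "empirical" else "")
    return SubstitutionModel(S, [(pi, 1.0)], alpha=alpha, K=K,
                             frequency_mode=mode, name=name)


def mixture_model(profiles: list[tuple[np.ndarray, float]],
                  alpha: float = 1.0, K: int = 4,
                  name: str = "") -> SubstitutionModel:
    """LG exchangeabilities with a fixed-weight profile mixture."""
    S, _ = load_lg()
    return SubstitutionModel(S, profiles, alpha=alpha, K=K,
                             name=name or f"LG+C{len(profiles)}+G{K}")


def equal_rates_model(alpha: float = 1.0, K: int = 1) -> SubstitutionModel:
    """20-state equal-rates chain (uniform frequencies, all-ones S).

    The amino-acid analogue of Jukes-Cantor; has the closed form
    p_same(t) = 1/20 + (19/20)·exp(−20t/19), used as an analytic oracle.
    """
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return SubstitutionModel(S, [(pi, 1.0)], alpha=alpha, K=K, name="EQ")


def read_profiles(path) -> list[tuple[np.ndarray, float]]:
    """Read a profile-set file: per line, 20 frequencies then a weight."""
    profiles = []
    for ln in open(path, encoding="utf-8"):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        vals = [float(x) for x in ln.split()]
        if len(vals) != N_STATES + 1:
            raise ModelError("profile lines need 20 frequencies + 1 weight")
        profiles.append((np.array(vals[:N_STATES]), vals[N_STATES]))
    if not profiles:
        raise ModelError("no profiles in file")
    total = sum(w for _, w in profiles)
    return [(p, w / total) for p, w in profiles]


def write_profiles(profiles, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# 20 amino-acid frequencies (alphabetical) + mixture weight per line\n")
        for pi, w in profiles:
            fh.write(" ".join(f"{x:.8g}" for x in pi) + f" {w:.8g}\n")
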