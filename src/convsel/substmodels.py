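"""Time-reversible substitution models for amino acids and codons.

Rate matrices are built from symmetric exchangeabilities and stationary
frequencies (GTR form), so detailed balance holds by construction.  Matrix
exponentials use the symmetrized eigen-decomposition: with
``B = diag(sqrt(pi)) Q diag(1/sqrt(pi))`` symmetric, ``P(t) = exp(Qt)`` is
recovered from the spectrum of ``B``; the decomposition is cached per Q and
reused across branches, which is what makes mixture fitting affordable.

Codon models follow the standard parameterisation: entries are zero for
multi-nucleotide changes and proportional to the target codon frequency,
multiplied by ``kappa`` for transitions and ``omega`` for nonsynonymous
changes.  Equilibrium codon frequencies may come from position-specific
nucleotide counts (F3x4, the default for the selection screen), pooled
nucleotide counts (F1x4), or observed codon counts (F61).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._dayhoff import dayhoff_exchangeabilities, dayhoff_frequencies
from .genetics import (
    AA_INDEX,
    CODON_NDIFF,
    CODON_SYNONYMOUS,
    CODON_TRANSITION,
    N_AA,
    N_CODONS,
    SENSE_CODONS,
)

_FREQ_FLOOR = 1e-10


def _gtr_rate_matrix(exchange: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Unscaled GTR rate matrix from exchangeabilities and frequencies."""
    q = exchange * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def expected_rate(q: np.ndarray, freqs: np.ndarray) -> float:
    """Expected substitutions per unit time at stationarity."""
    return float(-np.sum(freqs * np.diag(q)))


class EigenQ:
    """Cached spectral decomposition of a reversible rate matrix.

    Provides vectorized transition matrices for arrays of branch lengths.
    """

    def __init__(self, q: np.ndarray, freqs: np.ndarray):
        self.q = q
        self.freqs = freqs
        sq = np.sqrt(freqs)
        b = (sq[:, None] * q) / sq[None, :]
        b = 0.5 * (b + b.T)  # symmetrize away rounding noise
        w, u = np.linalg.eigh(b)
        self._w = w
        self._left = u / sq[:, None] * 1.0  # diag(1/sqrt(pi)) U
        self._right = (u * sq[:, None]).T  # U^T diag(sqrt(pi))

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for each t in ``ts``; shape (len(ts), S, S)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be >= 0")
        e = np.exp(self._w[None, :] * ts[:, None])  # (B, S)
        p = (self._left[None, :, :] * e[:, None, :]) @ self._right
        np.clip(p, 0.0, None, out=p)
        return p

    def transition_matrix(self, t: float) -> np.ndarray:
        return self.transition_matrices(np.array([t]))[0]


@dataclass
class AminoAcidModel:
    """Reversible 20-state amino-acid replacement model, scaled to rate 1."""

    exchange: np.ndarray
    freqs: np.ndarray
    q: np.ndarray = field(init=False)
    _eig: EigenQ = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.exchange.shape != (N_AA, N_AA) or not np.allclose(
            self.exchange, self.exchange.T
        ):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("stationary frequencies must sum to 1")
        q = _gtr_rate_matrix(self.exchange, self.freqs)
        q /= expected_rate(q, self.freqs)
        self.q = q
        self._eig = EigenQ(q, self.freqs)

    def transition_matrix(self, t: float) -> np.ndarray:
        return self._eig.transition_matrix(t)

    @property
    def eig(self) -> EigenQ:
        return self._eig


def dayhoff_model(
    freq_mode: str = "model_builtin", alignment_freqs: np.ndarray | None = None
) -> AminoAcidModel:
    """The Dayhoff replacement model.

    ``model_builtin`` uses the published equilibrium frequencies;
    ``empirical_from_alignment`` takes frequencies observed in an alignment
    (pass raw counts or frequencies); zero counts for observed states get
    add-one smoothing with a warning.
    """
    exchange = dayhoff_exchangeabilities()
    if freq_mode == "model_builtin":
        freqs = dayhoff_frequencies()
    elif freq_mode == "empirical_from_alignment":
        if alignment_freqs is None:
            raise ValueError("empirical mode requires alignment frequencies/counts")
        counts = np.asarray(alignment_freqs, dtype=float)
        if counts.sum() <= 0:
            raise ValueError("alignment contains no unambiguous residues")
        if np.any(counts == 0):
            warnings.warn(
                "zero observed frequency for some amino acids; "
                "applying add-one smoothing",
                stacklevel=2,
            )
            scale = counts.sum() / max(counts[counts > 0].min(), 1.0)
            counts = counts * scale + 1.0
        freqs = counts / counts.sum()
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    return AminoAcidModel(exchange, freqs)


@dataclass
class CodonModel:
    """Muse–Gaut/Goldman–Yang style codon model with kappa and omega.

    ``scale`` divides the rate matrix; pass 1.0 (default) for an unscaled
    matrix, or a mixture-level factor so branch lengths read as expected
    substitutions per codon averaged over site classes.
    """

    kappa: float
    omega: float
    codon_freqs: np.ndarray
    scale: float = 1.0
    q: np.ndarray = field(init=False)
    _eig: EigenQ | None = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if not self.omega >= 0:
            raise ValueError("omega must be >= 0")
        f = np.asarray(self.codon_freqs, dtype=float)
        if f.shape != (N_CODONS,):
            raise ValueError(f"codon_freqs must have length {N_CODONS}")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("codon frequencies must sum to 1 (tolerance 1e-8)")
        self.codon_freqs = f
        self.q = codon_rate_matrix(self.kappa, self.omega, f) / self.scale

    @property
    def eig(self) -> EigenQ:
        if self._eig is None:
            self._eig = EigenQ(self.q, self.codon_freqs)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        return self.eig.transition_matrix(t)


def codon_rate_matrix(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    """Unscaled codon rate matrix; zero for multi-nucleotide changes."""
    q = np.where(CODON_NDIFF == 1, freqs[None, :], 0.0)
    q = np.where(CODON_TRANSITION, q * kappa, q)
    q = np.where(CODON_SYNONYMOUS, q, q * omega)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


# ---------------------------------------------------------------------------
# Codon equilibrium frequency estimators
# ---------------------------------------------------------------------------


def _position_nucleotide_counts(codon_seqs: list[str]) -> np.ndarray:
    counts = np.zeros((3, 4))
    order = "TCAG"
    for seq in codon_seqs:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            for pos in range(3):
                ch = seq[i + pos]
                if ch in order:
                    counts[pos, order.index(ch)] += 1
    return counts


def f3x4_frequencies(codon_seqs: list[str]) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts."""
    counts = _position_nucleotide_counts(codon_seqs) + 1.0  # pseudocount
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    return _codon_freqs_from_positions(pos_freqs)


def f1x4_frequencies(codon_seqs: list[str]) -> np.ndarray:
    """F1x4 codon frequencies from pooled nucleotide counts."""
    counts = _position_nucleotide_counts(codon_seqs).sum(axis=0) + 1.0
    f = counts / counts.sum()
    return _codon_freqs_from_positions(np.tile(f, (3, 1)))


def _codon_freqs_from_positions(pos_freqs: np.ndarray) -> np.ndarray:
    order = "TCAG"
    raw = np.array(
        [
            pos_freqs[0, order.index(c[0])]
            * pos_freqs[1, order.index(c[1])]
            * pos_freqs[2, order.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    raw = np.maximum(raw, _FREQ_FLOOR)
    return raw / raw.sum()


def f61_frequencies(codon_seqs: list[str]) -> np.ndarray:
    """Empirical codon frequencies with add-one smoothing."""
    counts = np.ones(N_CODONS)
    from .genetics import CODON_INDEX

    for seq in codon_seqs:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            idx = CODON_INDEX.get(seq[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def aa_counts(protein_seqs: list[str]) -> np.ndarray:
    """Counts of unambiguous residues, for empirical Dayhoff frequencies."""
    counts = np.zeros(N_AA)
    for seq in protein_seqs:
        for ch in seq:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts
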