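"""Three-state copy-number HMM with distance-dependent transitions.

States are copy number 1 (heterozygous deletion), 2 (normal diploid) and 3
(duplication) per target exon.  Two properties of the chain are deliberate:

* the initial distribution gives the first exon on each chromosome the same
  prior probability ``q`` of being in a CNV state as any other exon, so
  variants affecting the first exon are detectable; and
* transition probabilities depend on the genomic distance ``d`` between
  adjacent targets, interpolating between full persistence of a CNV state at
  ``d = 0`` and complete independence (rows equal to the prior) as
  ``d -> infinity`` — exons far apart are treated independently because a
  germline CNV is unlikely to span them.

With ``e = exp(-d / L)`` the transition matrix over (del, normal, dup) is::

    normal row:   (q,            1 - 2q,            q)
    del row:      (e + (1-e) q,  (1-e)(1 - 2q),     (1-e) q)
    dup row:      ((1-e) q,      (1-e)(1 - 2q),     e + (1-e) q)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DELETION",
    "NORMAL",
    "DUPLICATION",
    "STATE_NAMES",
    "COPY_NUMBERS",
    "HMMParams",
    "state_mean",
    "transition_matrix",
    "initial_distribution",
    "viterbi",
]

DELETION, NORMAL, DUPLICATION = 0, 1, 2
STATE_NAMES = ("deletion", "normal", "duplication")
COPY_NUMBERS = (1, 2, 3)

# Tie preference for Viterbi decoding: conservative, normal first.
_TIE_ORDER = (NORMAL, DELETION, DUPLICATION)


@dataclass(frozen=True)
class HMMParams:
    """Transition model parameters.

    cnv_rate
        Prior per-step probability ``q`` of entering each CNV state; trades
        sensitivity against false discovery.
    cnv_length_bp
        Expected germline CNV span ``L`` in bp, setting the distance scale of
        the persistence decay.
    """

    cnv_rate: float = 0.01
    cnv_length_bp: float = 50_000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cnv_rate < 0.5:
            raise ValueError(f"cnv_rate must be in (0, 0.5), got {self.cnv_rate}")
        if not self.cnv_length_bp > 0:
            raise ValueError(
                f"cnv_length_bp must be positive, got {self.cnv_length_bp}"
            )


def state_mean(mu: float, c: int) -> float:
    """Expected test-read proportion at copy number ``c``.

    Scales the odds of the normal-copy proportion ``mu`` by ``c / 2``:
    ``c*mu / (c*mu + 2*(1-mu))``; ``c = 2`` returns ``mu`` unchanged.
    """
    if c not in COPY_NUMBERS:
        raise ValueError(f"copy number must be one of {COPY_NUMBERS}, got {c}")
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must be in (0, 1), got {mu}")
    return c * mu / (c * mu + 2.0 * (1.0 - mu))


def transition_matrix(d: float, params: HMMParams) -> np.ndarray:
    """3x3 stochastic matrix over (del, normal, dup) for a gap of ``d`` bp.

    ``d = inf`` (chromosome change) makes every row equal to the prior
    (q, 1-2q, q), i.e. adjacent targets independent.
    """
    if d < 0:
        raise ValueError(f"gap must be >= 0, got {d}")
    q = params.cnv_rate
    e = math.exp(-d / params.cnv_length_bp) if math.isfinite(d) else 0.0
    normal_row = (q, 1.0 - 2.0 * q, q)
    return np.array(
        [
            (e + (1 - e) * q, (1 - e) * (1 - 2 * q), (1 - e) * q),
            normal_row,
            ((1 - e) * q, (1 - e) * (1 - 2 * q), e + (1 - e) * q),
        ]
    )


def initial_distribution(params: HMMParams) -> np.ndarray:
    """Prior over states for the first target on a chromosome: (q, 1-2q, q)."""
    q = params.cnv_rate
    return np.array([q, 1.0 - 2.0 * q, q])


def _argmax_tie(scores: np.ndarray) -> int:
    best = _TIE_ORDER[0]
    for s in _TIE_ORDER[1:]:
        if scores[s] > scores[best]:
            best = s
    return best


def viterbi(
    emissions: np.ndarray,
    gaps: np.ndarray,
    params: HMMParams,
) -> np.ndarray:
    """Maximum-a-posteriori state path (log-space Viterbi).

    ``emissions`` is (K, 3) log-likelihoods in HMM target order; ``gaps`` has
    length K-1 with ``inf`` at chromosome boundaries.  Ties are broken in
    favour of normal, then deletion.
    """
    emissions = np.asarray(emissions, dtype=float)
    if emissions.size == 0:
        return np.zeros(0, dtype=np.int64)
    if emissions.ndim != 2 or emissions.shape[1] != 3:
        raise ValueError("emissions must be a (K, 3) array")
    if not np.isfinite(emissions).all():
        raise ValueError("emissions must be finite")
    K = emissions.shape[0]
    gaps = np.asarray(gaps, dtype=float)
    if gaps.shape != (K - 1,):
        raise ValueError(f"gaps must have length {K - 1}, got {gaps.shape}")

    delta = np.log(initial_distribution(params)) + emissions[0]
    psi = np.zeros((K, 3), dtype=np.int64)
    for k in range(1, K):
        with np.errstate(divide="ignore"):
            logT = np.log(transition_matrix(gaps[k - 1], params))
        new = np.empty(3)
        for j in range(3):
            scores = delta + logT[:, j]
            i = _argmax_tie(scores)
            psi[k, j] = i
            new[j] = scores[i] + emissions[k, j]
        delta = new

    path = np.empty(K, dtype=np.int64)
    path[-1] = _argmax_tie(delta)
    for k in range(K - 1, 0, -1):
        path[k - 1] = psi[k, path[k]]
    return path
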