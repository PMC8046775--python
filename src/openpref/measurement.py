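"""Projective measurement, choice-induced collapse, decay-rescaled timing and
the rating/strength output mapping.

A binary choice is a coarse projective measurement splitting the level ladder
at the midpoint: the right-choice projector has 1 on every level above
``mid``, the left-choice projector 1 on every level below, and both carry
``sqrt(1/2)`` at ``mid`` so that the neutral level contributes half its
population to each side (and ``P_L^2 + P_R^2 = I``).  Observing a choice
collapses the state by the Lüders rule ``P rho P / Pr``; a no-choice motor
response leaves the state untouched.  Ratings are fine-grained level
measurements whose magnitudes are produced by a logistic map of the distance
from the midpoint.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .dynamics import ModelParams, PreferenceScale

Response = Literal["L", "R"]

#: decay-time conventions for the second evolution stage (see
#: :func:`effective_duration`)
DECAY_CONVENTIONS = ("post_response", "literal")


def choice_projectors(scale: PreferenceScale) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal projectors ``(P_L, P_R)`` for the binary choice measurement."""
    n, mid = scale.n, scale.mid
    dL = np.zeros(n)
    dR = np.zeros(n)
    dL[: mid - 1] = 1.0
    dR[mid:] = 1.0
    dL[mid - 1] = dR[mid - 1] = np.sqrt(0.5)
    return np.diag(dL), np.diag(dR)


def rating_projector(scale: PreferenceScale, level: int) -> np.ndarray:
    """Projector ``P_j`` onto a single rating level (1-based)."""
    if not 1 <= level <= scale.n:
        raise ValueError(f"level {level} outside 1..{scale.n}")
    P = np.zeros((scale.n, scale.n))
    P[level - 1, level - 1] = 1.0
    return P


def choice_probabilities(rho: np.ndarray,
                         scale: PreferenceScale) -> tuple[float, float]:
    """Probabilities ``(pL, pR)`` of the two choice outcomes.

    ``Pr(R) = Tr(P_R rho P_R^dagger)``; for the diagonal projectors used here
    this sums the populations above the midpoint plus half the midpoint
    population.
    """
    PL, PR = choice_projectors(scale)
    dL = np.diag(PL) ** 2
    dR = np.diag(PR) ** 2
    pops = np.real(np.diag(rho))
    pL = float(dL @ pops)
    pR = float(dR @ pops)
    return pL, pR


def collapse(rho: np.ndarray, response: Response,
             scale: PreferenceScale) -> np.ndarray:
    """Lüders-rule collapse ``P rho P^dagger / Pr(response)``.

    The Hermiticity-preserving two-sided form is used (a single one-sided
    projector application would leave a coherent state non-Hermitian) and
    reproduces the same outcome probabilities.
    """
    PL, PR = choice_projectors(scale)
    P = PR if response == "R" else PL
    pL, pR = choice_probabilities(rho, scale)
    pr = pR if response == "R" else pL
    if pr <= 1e-300:
        raise ZeroDivisionError(
            f"response {response!r} has zero probability: degenerate measurement"
        )
    return P @ rho @ P / pr


def effective_duration(t2: float, t1: float, lambda_decay: float,
                       convention: str = "post_response") -> float:
    """Attention-decay-rescaled duration of the second evolution stage.

    Attention to the options drops out at constant rate ``lambda_decay``
    after the first response, so a nominal delay ``d = t2 - t1`` yields only
    ``d * exp(-lambda * d)`` seconds of effective evolution (the default
    ``post_response`` clock).  The ``literal`` convention instead rescales the
    absolute rating time, ``tau2 = t2 * exp(-lambda * d)``, and returns
    ``tau2 - t1`` floored at zero (the printed form can place the effective
    rating time before the first response at large decay rates).
    """
    if t1 < 0 or t2 < t1:
        raise ValueError(f"need t2 >= t1 >= 0, got t1={t1}, t2={t2}")
    d = t2 - t1
    decay = np.exp(-lambda_decay * d)
    if convention == "post_response":
        return d * decay
    if convention == "literal":
        return max(t2 * decay - t1, 0.0)
    raise ValueError(f"unknown decay convention {convention!r}")


def rating_distribution(rho: np.ndarray) -> np.ndarray:
    """Probability of each rating level, ``Pr(j) = Tr(P_j rho) = rho[j, j]``."""
    p = np.real(np.diag(rho)).copy()
    p[p < 0] = 0.0
    return p / p.sum()


def strength_map(scale: PreferenceScale, s_max: float) -> np.ndarray:
    """Diagonal of the logistic preference-strength map.

    ``S[j] = s_max / (1 + exp(-|j - mid|))``: the midpoint maps to
    ``s_max / 2`` and strength saturates toward ``s_max`` with distance from
    neutrality, so every model strength lies in ``[s_max / 2, s_max)``.
    """
    j = scale.level_index.astype(float)
    return s_max / (1.0 + np.exp(-np.abs(j - scale.mid)))


def expected_strength(rho: np.ndarray, smap: np.ndarray) -> float:
    """Mean preference strength ``S = Tr(S_range rho)`` in rating points."""
    return float(smap @ np.real(np.diag(rho)))
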