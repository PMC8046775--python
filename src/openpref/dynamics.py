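"""Open-system preference dynamics: generators and density-matrix propagation.

The decision maker's preference over two options is represented on ``n``
discrete latent levels (level 1 = "definitely prefer the option on the left",
level ``n`` = "definitely prefer the option on the right").  The state is an
``n x n`` density matrix ``rho`` mixing *epistemic* uncertainty (a classical
probability over pure states) with *ontic* uncertainty (complex amplitudes of
each pure state over the levels).  It evolves under a hybrid generator

    d rho / dt = -i (1 - alpha) [H, rho] + alpha * L(rho)

where ``H`` is a tridiagonal Hamiltonian (quantum-walk part, producing
oscillation and interference), ``L`` is a Lindblad dissipator whose jump rates
are read off a classical birth-death intensity matrix ``K`` (Markov
random-walk part, producing monotone relaxation), and ``alpha`` in [0, 1]
mixes the two: ``alpha = 0`` is a pure quantum walk, ``alpha = 1`` a pure
continuous-time Markov chain on the diagonal of ``rho``.

Propagation uses the matrix-exponential solution of the flattened (vectorised)
master equation; the spectral decomposition of the superoperator is cached on
the generator so that evolving to many time points costs two matrix-vector
products each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

logger = logging.getLogger("openpref")

#: absolute tolerance for density-matrix invariant checks
RHO_TOL = 1e-8
#: trace drift above which evolve() renormalises
TRACE_RENORM_TOL = 1e-10


# ---------------------------------------------------------------------------
# scales and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreferenceScale:
    """A discrete, odd-sized ladder of latent preference levels.

    Levels are 1-based; the midpoint level ``mid = (n + 1) / 2`` is the
    neutral state, equidistant from "definitely left" (1) and "definitely
    right" (n).
    """

    n: int

    def __post_init__(self) -> None:
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError(f"n must be odd and >= 3, got {self.n}")

    @property
    def mid(self) -> int:
        return (self.n + 1) // 2

    @property
    def level_index(self) -> np.ndarray:
        """1-based level labels ``1..n``."""
        return np.arange(1, self.n + 1)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the open-system model for one condition's dynamics.

    Units: drifts and diffusions are rates (1/s) on the level ladder,
    ``lambda_decay`` is the attention-decay rate (1/s), ``s_v`` the initial
    truncated-normal spread in levels, ``s_max`` the rating-scale maximum
    (30 or 10 points).
    """

    mu_q: float
    sigma_q: float
    mu_m: float
    sigma_m: float
    alpha: float
    lambda_decay: float
    s_v: float
    n: int = 21
    s_max: float = 30.0

    def __post_init__(self) -> None:
        PreferenceScale(self.n)  # validates n
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.sigma_q < 0:
            raise ValueError("sigma_q must be nonnegative")
        if self.sigma_m < abs(self.mu_m):
            raise ValueError(
                "sigma_m must be >= |mu_m| so all Lindblad rates "
                f"sigma_m +/- mu_m are nonnegative (got sigma_m={self.sigma_m}, "
                f"mu_m={self.mu_m})"
            )
        if self.lambda_decay < 0:
            raise ValueError("lambda_decay must be nonnegative")
        if self.s_v <= 0:
            raise ValueError("s_v must be positive")
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")

    @property
    def scale(self) -> PreferenceScale:
        return PreferenceScale(self.n)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "mu_Q": self.mu_q, "sigma_Q": self.sigma_q,
            "mu_M": self.mu_m, "sigma_M": self.sigma_m,
            "alpha": self.alpha, "lambda": self.lambda_decay,
            "s_v": self.s_v, "n": self.n, "S_max": self.s_max,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        return cls(
            mu_q=float(d["mu_Q"]), sigma_q=float(d["sigma_Q"]),
            mu_m=float(d["mu_M"]), sigma_m=float(d["sigma_M"]),
            alpha=float(d["alpha"]), lambda_decay=float(d["lambda"]),
            s_v=float(d["s_v"]), n=int(d.get("n", 21)),
            s_max=float(d.get("S_max", 30.0)),
        )


# ---------------------------------------------------------------------------
# generator construction
# ---------------------------------------------------------------------------

_BASIS_CACHE: dict[int, tuple] = {}


def _hermitian_basis(n: int):
    """Sparse orthonormal basis of Hermitian n x n matrices (flattened).

    Returns ``(B, Bh)`` with ``B`` the ``n^2 x n^2`` sparse matrix whose
    columns are the flattened basis elements (the ``n`` diagonal units, then
    for each pair a < b the symmetric element ``(E_ab + E_ba)/sqrt(2)`` and
    the antisymmetric element ``i (E_ab - E_ba)/sqrt(2)``) and ``Bh`` its
    conjugate transpose.  Cached per ``n``.
    """
    from scipy import sparse

    cached = _BASIS_CACHE.get(n)
    if cached is None:
        rows, cols, vals = [], [], []
        for a in range(n):
            rows.append(a * n + a); cols.append(a); vals.append(1.0 + 0j)
        col = n
        r = 1.0 / np.sqrt(2.0)
        for a in range(n):
            for b in range(a + 1, n):
                rows += [a * n + b, b * n + a]
                cols += [col, col]
                vals += [r + 0j, r + 0j]
                col += 1
                rows += [a * n + b, b * n + a]
                cols += [col, col]
                vals += [1j * r, -1j * r]
                col += 1
        B = sparse.csr_matrix(
            (np.array(vals), (np.array(rows), np.array(cols))),
            shape=(n * n, n * n))
        cached = (B, B.conj().T.tocsr())
        _BASIS_CACHE[n] = cached
    return cached

def build_hamiltonian(params: ModelParams) -> np.ndarray:
    """Tridiagonal Hamiltonian of the quantum-walk part.

    The diagonal is the linear potential ``H[j, j] = j * mu_q`` (1-based
    level index ``j``; only the slope matters, the intercept is dynamically
    irrelevant) and every super-/sub-diagonal entry is ``sigma_q``.
    """
    n = params.n
    j = np.arange(1, n + 1, dtype=float)
    H = np.diag(j * params.mu_q)
    if n > 1:
        off = np.full(n - 1, params.sigma_q)
        H += np.diag(off, 1) + np.diag(off, -1)
    return H


def build_intensity(params: ModelParams) -> np.ndarray:
    """Tridiagonal intensity matrix K of the classical birth-death chain.

    Column ``j`` carries the outflow rates of level ``j``: up-flow (toward
    higher levels) ``sigma_m + mu_m``, down-flow ``sigma_m - mu_m``, diagonal
    chosen so each column sums to zero (probability conservation); boundary
    columns only lose mass in the one available direction.
    """
    if params.sigma_m < abs(params.mu_m):
        raise ValueError("sigma_m must be >= |mu_m|")
    n = params.n
    up = params.sigma_m + params.mu_m      # j -> j+1
    down = params.sigma_m - params.mu_m    # j -> j-1
    K = np.zeros((n, n))
    for c in range(n):
        if c > 0:
            K[c - 1, c] = down
        if c < n - 1:
            K[c + 1, c] = up
        K[c, c] = -(K[:, c].sum() - K[c, c])
    return K


def _centered_hamiltonian(params: ModelParams) -> np.ndarray:
    """H with the (dynamically irrelevant) diagonal mean removed.

    Keeps the superoperator spectrum centred, which improves the numerical
    conditioning of its eigendecomposition for large drifts.
    """
    H = build_hamiltonian(params)
    np.fill_diagonal(H, H.diagonal() - H.diagonal().mean())
    return H


@dataclass
class LindbladGenerator:
    """Flattened generator of the open-system master equation.

    ``superoperator`` is the ``n^2 x n^2`` complex matrix ``G`` acting on the
    row-major-flattened density matrix, ``rates`` the nonnegative jump rates
    ``gamma[i, j]`` (transition j -> i) taken from the off-diagonal band of K.
    """

    superoperator: np.ndarray
    alpha: float
    rates: np.ndarray
    n: int
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def spectral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cached eigendecomposition ``(w, V, Vinv)`` of the superoperator.

        The generator preserves Hermiticity, so it is diagonalised in an
        orthonormal Hermitian-matrix basis where it is real — a real
        eigendecomposition is ~3x faster than a complex one at n = 21 and
        the result is transformed back to the flattened complex basis.
        """
        if self._eig is None:
            B, Bh = _hermitian_basis(self.n)
            M1 = Bh @ self.superoperator            # sparse @ dense
            R = (B.T @ M1.T).T                      # == M1 @ B
            imag = np.abs(R.imag).max()
            if imag > 1e-9 * max(1.0, np.abs(R.real).max()):
                # not Hermiticity-preserving (should not happen): fall back
                w, V = np.linalg.eig(self.superoperator)
                self._eig = (w, V, np.linalg.inv(V))
                return self._eig
            w, U = np.linalg.eig(np.ascontiguousarray(R.real))
            V = B @ U
            Vinv = (B.conj() @ np.linalg.inv(U).T).T    # == inv(U) @ Bh
            self._eig = (w, V, Vinv)
        return self._eig


def build_generator(params: ModelParams) -> LindbladGenerator:
    """Assemble the hybrid generator G = -i(1-a)[H, .] + a * L(.).

    The jump operators are the unit matrices ``L_ij = E_ij`` with rates
    ``gamma_ij = K[i, j]`` for ``i != j`` (and ``gamma_ii = 0``); this is the
    unique assignment under which the ``alpha = 1`` diagonal dynamics reduce
    to the classical master equation ``dp/dt = K p``.
    """
    n = params.n
    I = np.eye(n)
    H = _centered_hamiltonian(params)
    G = -1j * (1.0 - params.alpha) * (np.kron(H, I) - np.kron(I, H.T))

    K = build_intensity(params)
    gamma = K.copy()
    np.fill_diagonal(gamma, 0.0)

    # gain term: sum_ij gamma_ij E_ij rho E_ji only couples rho[j, j] -> rho[i, i]
    Gr = np.zeros((n * n, n * n))
    ii, jj = np.nonzero(gamma)
    Gr[ii * n + ii, jj * n + jj] = gamma[ii, jj]
    # loss term: -(1/2) {sum_ij gamma_ij E_jj, rho} is diagonal in the flattened basis
    col_rates = gamma.sum(axis=0)          # Gamma_j = total outflow rate of level j
    D = np.diag(col_rates)
    Gr -= 0.5 * (np.kron(D, I) + np.kron(I, D))

    G = G + params.alpha * Gr
    return LindbladGenerator(superoperator=G, alpha=params.alpha,
                             rates=gamma, n=n)


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------

def initial_state(params: ModelParams) -> np.ndarray:
    """Pure unbiased starting state rho(t0) = psi0 psi0^dagger.

    ``psi0[j]`` is the square root of a truncated-normal weight profile over
    the integer levels: the normal density with mean ``mid`` and standard
    deviation ``s_v`` evaluated at each level and renormalised to sum to one.
    """
    scale = params.scale
    j = scale.level_index.astype(float)
    w = np.exp(-0.5 * ((j - scale.mid) / params.s_v) ** 2)
    w /= w.sum()
    psi = np.sqrt(w)
    return np.outer(psi, psi).astype(complex)


def validate_density(rho: np.ndarray, tol: float = RHO_TOL) -> None:
    """Raise if ``rho`` is not Hermitian, unit-trace, PSD (to ``tol``)."""
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("density matrix must be square")
    herm = np.abs(rho - rho.conj().T).max()
    if herm > tol:
        raise ValueError(f"density matrix not Hermitian (deviation {herm:.2e})")
    tr = np.real(np.trace(rho))
    if abs(tr - 1.0) > tol:
        raise ValueError(f"density matrix trace {tr} != 1")
    lo = np.linalg.eigvalsh(0.5 * (rho + rho.conj().T)).min()
    if lo < -tol:
        raise ValueError(f"density matrix has negative eigenvalue {lo:.2e}")


def evolve(rho: np.ndarray, gen: LindbladGenerator, duration: float) -> np.ndarray:
    """Propagate ``rho`` for ``duration`` seconds: exp(G t) applied in the
    flattened representation, then reshaped.

    The output is symmetrised and trace-renormalised when floating-point
    drift exceeds :data:`TRACE_RENORM_TOL`; tiny negative eigenvalues are the
    caller's concern (see :func:`validate_density`).
    """
    if duration < 0:
        raise ValueError(f"duration must be nonnegative, got {duration}")
    if duration == 0:
        return rho.copy()
    w, V, Vinv = gen.spectral()
    with np.errstate(over="ignore", invalid="ignore"):
        v = Vinv @ rho.reshape(-1)
        v = V @ (np.exp(w * duration) * v)
    out = v.reshape(gen.n, gen.n)
    out = 0.5 * (out + out.conj().T)
    tr = np.real(np.trace(out))
    if abs(tr - 1.0) > TRACE_RENORM_TOL:
        if abs(tr - 1.0) > 1e-6:
            logger.warning("evolve: trace drifted to %.12f; renormalising", tr)
        out = out / tr
    return out


def evolved_diagonal(rho: np.ndarray, gen: LindbladGenerator,
                     durations: np.ndarray) -> np.ndarray:
    """Diagonals (level populations) of ``rho`` evolved to many durations.

    Returns an array of shape ``(len(durations), n)``.  Exploits the cached
    spectral decomposition: after one projection of ``rho`` onto the
    eigenbasis, each extra time point costs a single small matrix product.
    """
    durations = np.asarray(durations, dtype=float)
    if (durations < 0).any():
        raise ValueError("durations must be nonnegative")
    w, V, Vinv = gen.spectral()
    n = gen.n
    y = Vinv @ rho.reshape(-1)
    rows = V[(np.arange(n) * n + np.arange(n)), :]   # rows giving diag entries
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.real((np.exp(np.outer(durations, w)) * y) @ rows.T)
    # guard against tiny float drift
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return out
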