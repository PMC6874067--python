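"""Raw, central and discrete orthogonal Hahn moments of square matrices.

A numeric sequence of length L is laid out row-major in the smallest
square matrix that holds it (side ``m = ceil(sqrt(L))``, trailing cells
zero).  Three families of degree-≤3 moments summarise any such square
matrix (the sequence matrix itself, or the 20×20 position-relative
incidence matrices):

* raw moments     ``M_rs = Σ_a Σ_b a^r b^s P[a,b]`` (1-based cell
  coordinates, ``a`` the row index),
* central moments ``I_rs = Σ_a Σ_b (a − x̄)^r (b − ȳ)^s P[a,b]`` about
  the centroid ``x̄ = M10/M00``, ``ȳ = M01/M00``,
* Hahn moments    projections onto the weighted, unit-norm discrete
  Hahn polynomial basis on the support {0, …, m−1}.

Each family is reported as the ten coefficients with total degree
``r+s ≤ 3``, in the fixed order (0,0),(0,1),(0,2),(1,0),(1,1),(2,0),
(1,2),(2,1),(0,3),(3,0); a full block is the 30-value concatenation
raw ‖ central ‖ Hahn.

Hahn parameters default to ``u = z = 0``, for which the weight is
uniform and the polynomials reduce to the discrete Chebyshev (Gram)
family.  For integer parameters the polynomial table is evaluated in
exact rational arithmetic before normalisation, so orthonormality of
the basis holds to machine precision even at degree m−1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

logger = logging.getLogger(__name__)

#: (r, s) index pairs of the ten degree-≤3 moments, in reporting order.
MOMENT_ORDER: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (1, 0), (1, 1),
    (2, 0), (1, 2), (2, 1), (0, 3), (3, 0),
)

#: Minimum side length supporting a degree-3 orthogonal basis.
MIN_HAHN_SIDE = 4


@dataclass(frozen=True)
class MomentSet:
    """The ten ordered degree-≤3 coefficients of one moment family."""

    family: str  # 'raw' | 'central' | 'hahn'
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if self.family not in ("raw", "central", "hahn"):
            raise ValueError(f"unknown moment family {self.family!r}")
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.shape != (len(MOMENT_ORDER),):
            raise ValueError(
                f"expected {len(MOMENT_ORDER)} coefficients, got {coeffs.shape}"
            )
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("non-finite moment coefficients")
        object.__setattr__(self, "coefficients", coeffs)

    def __getitem__(self, rs: tuple[int, int]) -> float:
        return float(self.coefficients[MOMENT_ORDER.index(rs)])


def to_square_matrix(seq: np.ndarray) -> np.ndarray:
    """Lay a length-L sequence into the smallest square matrix.

    Side length is ``m = ceil(sqrt(L))``; values fill the matrix
    row-major and the trailing ``m² − L`` cells are zero.
    """
    seq = np.asarray(seq, dtype=float).ravel()
    if seq.size == 0:
        raise ValueError("cannot build a square matrix from an empty sequence")
    m = math.isqrt(seq.size - 1) + 1  # ceil(sqrt(L)) without float round-off
    out = np.zeros(m * m, dtype=float)
    out[: seq.size] = seq
    return out.reshape(m, m)


def _check_square(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1] or P.shape[0] < 1:
        raise ValueError(f"expected a square matrix, got shape {P.shape}")
    if not np.all(np.isfinite(P)):
        raise ValueError("matrix contains non-finite entries")
    return P


def raw_moments(P: np.ndarray) -> MomentSet:
    """Geometric moments ``M_rs`` with 1-based cell coordinates."""
    P = _check_square(P)
    m = P.shape[0]
    ax = np.arange(1, m + 1, dtype=float)
    coeffs = [
        float(ax**r @ P @ ax**s)  # Σ_a Σ_b a^r b^s P[a,b]
        for r, s in MOMENT_ORDER
    ]
    return MomentSet("raw", np.array(coeffs))


def central_moments(P: np.ndarray) -> MomentSet:
    """Centroid-centred moments ``I_rs``.

    A zero-mass matrix has no centroid; its central moments are defined
    as all-zero (with a logged warning) so degenerate all-padding
    windows stay representable.
    """
    P = _check_square(P)
    m = P.shape[0]
    ax = np.arange(1, m + 1, dtype=float)
    m00 = float(P.sum())
    if m00 == 0.0:
        logger.warning("zero-mass matrix: central moments defined as 0")
        return MomentSet("central", np.zeros(len(MOMENT_ORDER)))
    xbar = float(ax @ P.sum(axis=1)) / m00
    ybar = float(ax @ P.sum(axis=0)) / m00
    da, db = ax - xbar, ax - ybar
    coeffs = [float(da**r @ P @ db**s) for r, s in MOMENT_ORDER]
    return MomentSet("central", np.array(coeffs))


# ---------------------------------------------------------------------------
# Hahn polynomial basis
# ---------------------------------------------------------------------------

def _poch(a, i: int):
    """Rising factorial (a)_i = a (a+1) … (a+i−1); (a)_0 = 1.

    Direct product — the supports used here (m ≤ 64) need no log-gamma
    rearrangement, and the product is exact for Fraction inputs.
    """
    out = a**0  # 1 of the same numeric type
    for k in range(i):
        out = out * (a + k)
    return out


def hahn_polynomial(n: int, r: int, M: int, u: float = 0.0, z: float = 0.0):
    """Unnormalised Hahn polynomial ``H_n^{(u,z)}(r)`` on {0, …, M−1}.

    Evaluated through the terminating hypergeometric sum (the classical
    ₃F₂ form, with parameters ``u, z`` and ``N = M − 1``)

        H_n(r) = (M+z−1)_n (M−1)_n ·
                 Σ_{i=0}^{n} (−n)_i (n+u+z+1)_i (−r)_i
                             / [ (u+1)_i (−M+1)_i i! ]

    with rising-factorial (Pochhammer) terms.  The per-order prefactor
    is a scale convention only: downstream code relies on
    orthogonality, not scale, and divides it out when normalising.
    ``H_0 ≡ 1`` for every ``r, M, u, z``.  Integer ``u, z`` are
    evaluated in exact rational arithmetic.

    Parameters must satisfy ``0 ≤ n ≤ M−1``, ``0 ≤ r ≤ M−1`` and
    ``u, z > −1``.
    """
    if not (0 <= n <= M - 1):
        raise ValueError(f"order n={n} outside 0..{M - 1}")
    if not (0 <= r <= M - 1):
        raise ValueError(f"evaluation point r={r} outside 0..{M - 1}")
    if u <= -1 or z <= -1:
        raise ValueError("Hahn parameters must satisfy u, z > -1")
    exact = float(u).is_integer() and float(z).is_integer()
    if exact:
        u, z = Fraction(int(u)), Fraction(int(z))
    pref = _poch(M + z - 1, n) * _poch(M - 1, n)
    total = pref * 0
    for i in range(n + 1):
        num = _poch(-n, i) * _poch(n + u + z + 1, i) * _poch(-r, i)
        den = _poch(u + 1, i) * _poch(-(M - 1), i) * math.factorial(i)
        total += num / den
    value = pref * total
    return value if exact else float(value)


def _hahn_weight(r: int, M: int, u: float, z: float):
    """Orthogonality weight ρ(r) = Γ(u+r+1)Γ(z+M−r) / (Γ(r+1)Γ(M−r))."""
    if float(u).is_integer() and float(z).is_integer():
        num = math.factorial(int(u) + r) * math.factorial(int(z) + M - 1 - r)
        den = math.factorial(r) * math.factorial(M - 1 - r)
        return Fraction(num, den)
    return math.exp(
        math.lgamma(u + r + 1)
        + math.lgamma(z + M - r)
        - math.lgamma(r + 1)
        - math.lgamma(M - r)
    )


@lru_cache(maxsize=32)
def hahn_basis(M: int, u: float = 0.0, z: float = 0.0, orders: int | None = None) -> np.ndarray:
    """Weighted, unit-norm Hahn basis table on the support {0, …, M−1}.

    Returns an ``(orders, M)`` array ``B`` with
    ``B[n, r] = H_n(r) · sqrt(ρ(r)) / d_n`` where ``d_n²`` is the
    weighted squared norm of ``H_n``, so the rows are orthonormal under
    the plain Euclidean inner product.  The full-order table
    (``orders = M``) is an orthogonal matrix, which is what makes the
    transform invertible.
    """
    if M < 1:
        raise ValueError("support size must be >= 1")
    n_orders = M if orders is None else orders
    if not 1 <= n_orders <= M:
        raise ValueError(f"orders must be in 1..{M}")
    exact = float(u).is_integer() and float(z).is_integer()
    table = [
        [hahn_polynomial(n, r, M, u, z) for r in range(M)]
        for n in range(n_orders)
    ]
    weights = [_hahn_weight(r, M, u, z) for r in range(M)]
    if exact:
        # exact rational norms, then a single float sqrt per row/column
        sq_norms = [
            sum(h * h * w for h, w in zip(row, weights)) for row in table
        ]
        B = np.array(
            [
                [
                    float(h) * math.sqrt(float(w)) / math.sqrt(float(d2))
                    for h, w in zip(row, weights)
                ]
                for row, d2 in zip(table, sq_norms)
            ]
        )
    else:
        T = np.asarray(table, dtype=float)
        w = np.sqrt(np.asarray(weights, dtype=float))
        B = T * w
        B /= np.linalg.norm(B, axis=1, keepdims=True)
    return B


def hahn_moments(P: np.ndarray, u: float = 0.0, z: float = 0.0) -> MomentSet:
    """Degree-≤3 normalized Hahn moments of a square matrix.

    ``h_rs = Σ_a Σ_b P[a,b] H̃_r(b) H̃_s(a)`` over the orthonormal
    basis; requires side length ≥ 4 so a degree-3 basis exists.
    """
    P = _check_square(P)
    m = P.shape[0]
    if m < MIN_HAHN_SIDE:
        raise ValueError(
            f"matrix side {m} < {MIN_HAHN_SIDE}: no degree-3 Hahn basis"
        )
    B = hahn_basis(m, u, z, orders=MIN_HAHN_SIDE)
    C = B @ P @ B.T  # C[s, r] = Σ_a Σ_b H̃_s(a) P[a,b] H̃_r(b)
    coeffs = [C[s, r] for r, s in MOMENT_ORDER]
    return MomentSet("hahn", np.array(coeffs))


def hahn_transform(P: np.ndarray, u: float = 0.0, z: float = 0.0) -> np.ndarray:
    """Full-order Hahn coefficient matrix ``C`` with ``C[s, r] = h_rs``."""
    P = _check_square(P)
    B = hahn_basis(P.shape[0], u, z)
    return B @ P @ B.T


def hahn_inverse(C: np.ndarray, u: float = 0.0, z: float = 0.0) -> np.ndarray:
    """Reconstruct a matrix from its full-order Hahn coefficients."""
    C = _check_square(C)
    B = hahn_basis(C.shape[0], u, z)
    return B.T @ C @ B


def moment_block(P: np.ndarray, u: float = 0.0, z: float = 0.0) -> np.ndarray:
    """30 ordered reals: raw(10) ‖ central(10) ‖ Hahn(10) of one matrix."""
    return np.concatenate(
        [
            raw_moments(P).coefficients,
            central_moments(P).coefficients,
            hahn_moments(P, u, z).coefficients,
        ]
    )
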