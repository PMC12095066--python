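"""Classical and Schur-based dynamic mode decomposition of trait trajectories.

For one genotype the p x T trait-by-time matrix X is split into one-day
snapshot pairs (X1, X2) and a time-invariant linear operator A with
X2 ≈ A X1 is estimated:

* classical DMD: A = X2 X1†, the least-squares operator;
* Schur-based DMD: project onto the leading r POD modes of X1 = U Σ Vᵀ,
  form the reduced operator Ã = Uᵣᵀ X2 Vᵣ Σᵣ⁻¹, take its real Schur
  decomposition Ã = Qᵀ R Q, build projected modes Φ = X2 Vᵣ Σᵣ⁻¹ Qᵀ and the
  rank-r reconstruction A_r = Φ R Φ†.

The Schur route trades the severe overfitting of the dense p x p operator
for a low-rank, numerically stable surrogate whose factors (Φ, R) have few
entries — which is what makes them usable as traits in genomic prediction.

Because the SVD and the Schur decomposition are unique only up to signs and
block ordering, :func:`canonicalize_factors` puts every fitted model into a
canonical form so that entry (i, j) of a factor means the same thing in
every genotype.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.linalg import get_lapack_funcs

from .containers import TraitTensor

__all__ = [
    "SnapshotPair",
    "ClassicalDMDModel",
    "SchurDMDModel",
    "PredictedOperator",
    "build_snapshot_pair",
    "fit_classical_dmd",
    "fit_schur_dmd",
    "canonicalize_factors",
    "reconstruct_operator",
    "forecast_iterative",
    "forecast_recursive",
    "save_schur_model",
    "load_schur_model",
]

logger = logging.getLogger("dmdgp")


@dataclass
class SnapshotPair:
    """Aligned one-day snapshot matrices X1, X2 (p x n_pairs)."""

    X1: np.ndarray
    X2: np.ndarray
    pair_index: list[tuple[int, int]]  # (source, target) timepoint indices

    @property
    def n_pairs(self) -> int:
        return self.X1.shape[1]

    @property
    def n_traits(self) -> int:
        return self.X1.shape[0]


@dataclass
class ClassicalDMDModel:
    A: np.ndarray  # (p, p)
    rcond_used: float


@dataclass
class SchurDMDModel:
    """All factors of the Schur-based DMD for one genotype.

    Identities (within numerical tolerance): Uᵣ orthonormal columns,
    Q Qᵀ = I, Ã = Qᵀ R Q, A_r = Φ R Φ†, and the nonzero spectrum of A_r
    equals the spectrum of Ã.
    """

    r: int
    U_r: np.ndarray       # (p, r)
    Sigma_r: np.ndarray   # (r,) descending positive
    V_r: np.ndarray       # (n_pairs, r)
    A_tilde: np.ndarray   # (r, r)
    Q: np.ndarray         # (r, r) orthogonal, stored so that A_tilde = Qᵀ R Q
    R: np.ndarray         # (r, r) real quasi-upper-triangular
    Phi: np.ndarray       # (p, r) projected DMD modes
    A_r: np.ndarray       # (p, p)
    canonical: bool = False


@dataclass
class PredictedOperator:
    """Operator assembled from genomically predicted factor entries."""

    Phi_P: np.ndarray
    R_P: np.ndarray
    A_P: np.ndarray


# ---------------------------------------------------------------------------
# snapshot construction
# ---------------------------------------------------------------------------

def build_snapshot_pair(t: TraitTensor, line: str) -> SnapshotPair:
    """Gap-aware construction of (X1, X2) for one line.

    Within each measurement block, X1 takes every timepoint except the
    block's last and X2 every timepoint except the block's first, so each
    column pair spans exactly one calendar day and no pair crosses a gap.
    Blocks with a single timepoint contribute no pairs (warning).
    """
    X = t.line_matrix(line)
    cols1: list[int] = []
    cols2: list[int] = []
    for b in t.blocks:
        if len(b) < 2:
            warnings.warn(
                f"block at day {int(t.time_axis[b[0]])} has a single timepoint; skipped",
                stacklevel=2,
            )
            continue
        cols1.extend(b[:-1])
        cols2.extend(b[1:])
    if not cols1:
        raise ValueError(
            f"line {line!r}: no usable snapshot pairs; the operator is unidentifiable"
        )
    return SnapshotPair(X[:, cols1], X[:, cols2], list(zip(cols1, cols2)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _default_rcond(shape: tuple[int, int]) -> float:
    return max(shape) * np.finfo(float).eps


def fit_classical_dmd(s: SnapshotPair, rcond: float | None = None) -> ClassicalDMDModel:
    """A = X2 X1† — the Frobenius-optimal one-step operator."""
    if not (np.isfinite(s.X1).all() and np.isfinite(s.X2).all()):
        raise ValueError("snapshot matrices contain non-finite values")
    if rcond is None:
        rcond = _default_rcond(s.X1.shape)
    A = s.X2 @ np.linalg.pinv(s.X1, rcond=rcond)
    return ClassicalDMDModel(A=A, rcond_used=rcond)


def fit_schur_dmd(s: SnapshotPair, r: int = 2, canonicalize: bool = True) -> SchurDMDModel:
    """Schur-based DMD at retained rank ``r``.

    The stored ``Q`` satisfies Ã = Qᵀ R Q (so Q is the transpose of the
    orthogonal factor returned by a conventional real Schur routine); the
    projected modes are Φ = X2 Vᵣ Σᵣ⁻¹ Qᵀ, which makes A_r = Φ R Φ† share
    its nonzero spectrum with Ã.
    """
    if not (np.isfinite(s.X1).all() and np.isfinite(s.X2).all()):
        raise ValueError("snapshot matrices contain non-finite values")
    p, n = s.X1.shape
    if not 1 <= r <= min(p, n):
        raise ValueError(f"rank r={r} must be in [1, min(p, n_pairs)={min(p, n)}]")
    U, sv, Vt = np.linalg.svd(s.X1, full_matrices=False)
    if sv[r - 1] <= max(p, n) * np.finfo(float).eps * sv[0]:
        raise ValueError(
            f"singular value sigma_{r} is (numerically) zero; choose a smaller rank"
        )
    U_r, Sigma_r, V_r = U[:, :r], sv[:r], Vt[:r].T
    P = s.X2 @ (V_r / Sigma_r)          # = X2 Vᵣ Σᵣ⁻¹  (p x r)
    A_tilde = U_r.T @ P                 # (r, r)
    R, Z = scipy.linalg.schur(A_tilde, output="real")   # A_tilde = Z R Zᵀ
    Q = Z.T                             # A_tilde = Qᵀ R Q
    Phi = P @ Q.T                       # projected modes in the Schur basis
    A_r = reconstruct_operator(Phi, R)
    model = SchurDMDModel(
        r=r, U_r=U_r, Sigma_r=Sigma_r, V_r=V_r,
        A_tilde=A_tilde, Q=Q, R=R, Phi=Phi, A_r=A_r,
    )
    return canonicalize_factors(model) if canonicalize else model


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

def _quasi_blocks(R: np.ndarray, tol: float = 1e-12) -> list[tuple[int, int]]:
    """Diagonal-block partition (start, size) of a real quasi-triangular matrix."""
    r = R.shape[0]
    blocks = []
    i = 0
    while i < r:
        if i + 1 < r and abs(R[i + 1, i]) > tol * max(1.0, abs(R[i, i])):
            blocks.append((i, 2))
            i += 2
        else:
            blocks.append((i, 1))
            i += 1
    return blocks


def _block_modulus(R: np.ndarray, start: int, size: int) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(R[start:start + size, start:start + size]))))


def _order_schur_blocks(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal G with G.T @ R @ G quasi-triangular, blocks sorted by
    descending eigenvalue modulus (stable; ties keep original order)."""
    trexc = get_lapack_funcs(("trexc",), (R,))[0]
    Rw = np.asfortranarray(R.copy())
    G = np.asfortranarray(np.eye(R.shape[0]))
    pos = 0
    while pos < R.shape[0]:
        blocks = [(s, z) for (s, z) in _quasi_blocks(Rw) if s >= pos]
        moduli = [_block_modulus(Rw, s, z) for (s, z) in blocks]
        best = int(np.argmax(moduli))  # argmax is stable: first max wins
        src, size = blocks[best]
        if src != pos:
            Rw, G, info = trexc(Rw, G, src + 1, pos + 1)  # LAPACK is 1-based
            if info != 0:
                raise RuntimeError(f"Schur reordering failed (LAPACK info={info})")
            Rw = np.asfortranarray(Rw)
            G = np.asfortranarray(G)
        # re-derive the size at the target position: trexc may not split blocks
        pos += next(z for (s, z) in _quasi_blocks(Rw) if s == pos)
    return np.ascontiguousarray(Rw), np.ascontiguousarray(G)


def _orientation(col: np.ndarray) -> float:
    """Sign convention for a direction vector: +1 if the squared mass of the
    positive elements exceeds that of the negative ones.

    The functional sum(sign(v) * v^2) is continuous in v and odd under
    v -> -v, so nearby vectors (e.g. the same mode fitted in two similar
    genotypes) receive the same orientation — unlike an anchor based on the
    single largest-magnitude element, whose identity can switch between two
    near-tied elements of opposite sign and silently flip the column.
    """
    score = float(np.sum(np.sign(col) * col ** 2))
    if score != 0.0:
        return 1.0 if score > 0 else -1.0
    # perfectly balanced column: fall back to the largest-magnitude element
    return 1.0 if col[np.argmax(np.abs(col))] >= 0 else -1.0


def canonicalize_factors(m: SchurDMDModel) -> SchurDMDModel:
    """Resolve the sign and ordering indeterminacies of the factorization.

    Three orthogonal similarity/sign normalizations, each leaving A_r
    unchanged:

    1. each column of U_r is oriented positively (see :func:`_orientation`),
       with V_r, Ã and Q compensated;
    2. the diagonal blocks of R are reordered by descending eigenvalue
       modulus (Q and Φ compensated);
    3. each column of Φ is oriented positively (R and Q compensated).

    Without a fixed convention the same genotype could yield factor entries
    of arbitrary sign and order, destroying their across-genotype
    comparability (and hence their heritability).
    """
    U_r = m.U_r.copy(); V_r = m.V_r.copy()
    A_tilde = m.A_tilde.copy(); Q = m.Q.copy(); R = m.R.copy(); Phi = m.Phi.copy()

    # 1. SVD sign convention
    s = np.array([_orientation(U_r[:, j]) for j in range(m.r)])
    U_r *= s
    V_r *= s
    A_tilde = (A_tilde * s).T.copy()
    A_tilde = (A_tilde * s).T.copy()   # A_tilde <- D A_tilde D
    Q = Q * s                          # columns of Q scaled: Q <- Q D

    # 2. Schur block ordering by descending eigenvalue modulus
    R, G = _order_schur_blocks(R)
    Q = G.T @ Q
    Phi = Phi @ G

    # 3. Schur-basis sign convention via the projected modes
    d = np.array([_orientation(Phi[:, j]) for j in range(m.r)])
    Phi = Phi * d
    R = (R * d).T.copy()
    R = (R * d).T.copy()               # R <- D R D
    Q = (Q.T * d).T                    # rows of Q scaled: Q <- D Q

    return SchurDMDModel(
        r=m.r, U_r=U_r, Sigma_r=m.Sigma_r.copy(), V_r=V_r,
        A_tilde=A_tilde, Q=Q, R=R, Phi=Phi, A_r=m.A_r.copy(), canonical=True,
    )


# ---------------------------------------------------------------------------
# reconstruction and forecasting
# ---------------------------------------------------------------------------

def reconstruct_operator(Phi: np.ndarray, R: np.ndarray) -> np.ndarray:
    """A = Φ R Φ† with Φ† = (ΦᵀΦ)⁻¹Φᵀ for full column rank Φ."""
    Phi = np.asarray(Phi, dtype=float)
    R = np.asarray(R, dtype=float)
    if Phi.ndim != 2 or R.shape != (Phi.shape[1], Phi.shape[1]):
        raise ValueError(
            f"dimension mismatch: Phi {Phi.shape} vs R {R.shape}"
        )
    if np.linalg.matrix_rank(Phi) < Phi.shape[1]:
        logger.warning("Phi is rank-deficient; falling back to the pseudoinverse")
        warnings.warn("Phi is rank-deficient; using pseudoinverse", stacklevel=2)
        return Phi @ R @ np.linalg.pinv(Phi)
    Phi_pinv = np.linalg.solve(Phi.T @ Phi, Phi.T)
    return Phi @ R @ Phi_pinv


def _gap_steps(day_gap: int, gap_policy: str) -> int:
    if gap_policy == "unit_step":
        return 1
    if gap_policy == "power":
        return int(day_gap)
    raise ValueError(f"unknown gap_policy {gap_policy!r}")


def forecast_iterative(
    A: np.ndarray, t: TraitTensor, line: str, gap_policy: str = "unit_step"
) -> np.ndarray:
    """One-step-ahead predictions from measured states.

    Returns a p x (T-1) matrix: column j predicts timepoint j+1 from the
    measured state at timepoint j. Across a gap of g missing days,
    ``unit_step`` applies A once and ``power`` applies A^(g+1).
    """
    X = t.line_matrix(line)
    days = t.time_axis
    preds = np.empty((X.shape[0], X.shape[1] - 1))
    for j in range(X.shape[1] - 1):
        k = _gap_steps(int(days[j + 1] - days[j]), gap_policy)
        preds[:, j] = np.linalg.matrix_power(A, k) @ X[:, j]
    return preds


def forecast_recursive(
    A: np.ndarray,
    x_start: np.ndarray,
    steps: int,
    gap_policy: str = "unit_step",
    day_gaps: np.ndarray | None = None,
) -> np.ndarray:
    """Unroll predictions from a single measured state.

    ``day_gaps`` (length ``steps``) gives the calendar-day difference of each
    predicted timepoint from its predecessor (all ones by default). With
    ``gap_policy='power'`` the operator is applied once per calendar day;
    with ``unit_step`` once per measured step.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x_start, dtype=float)
    if day_gaps is None:
        day_gaps = np.ones(steps, dtype=int)
    day_gaps = np.asarray(day_gaps)
    if len(day_gaps) != steps:
        raise ValueError("day_gaps must have one entry per forecast step")
    out = np.empty((len(x), steps))
    for j in range(steps):
        k = _gap_steps(int(day_gaps[j]), gap_policy)
        for _ in range(k):
            x = A @ x
        if not np.isfinite(x).all():
            raise FloatingPointError(
                f"non-finite forecast at step {j + 1}; the operator is likely unstable"
            )
        out[:, j] = x
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = ("U_r", "Sigma_r", "V_r", "A_tilde", "Q", "R", "Phi", "A_r")


def save_schur_model(m: SchurDMDModel, path: str | Path) -> None:
    """Exact-round-trip JSON serialization of one fitted model."""
    payload = {"r": m.r, "canonical": m.canonical}
    for f in _ARRAY_FIELDS:
        arr = getattr(m, f)
        payload[f] = {"shape": list(arr.shape), "data": arr.ravel().tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_schur_model(path: str | Path) -> SchurDMDModel:
    with open(path) as fh:
        payload = json.load(fh)
    kwargs = {"r": payload["r"], "canonical": payload["canonical"]}
    for f in _ARRAY_FIELDS:
        spec = payload[f]
        kwargs[f] = np.array(spec["data"], dtype=float).reshape(spec["shape"])
    return SchurDMDModel(**kwargs)
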