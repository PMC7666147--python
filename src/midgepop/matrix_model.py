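"""Three-stage Leslie matrix model for a semelparous insect life cycle.

The life history is collapsed to egg -> larva -> adult, with a single
reproductive event per female (the adult dies after laying one egg mass).
The projection matrix is therefore a pure 3-cycle::

        [ 0    0    F  ]
    A = [ s_e  0    0  ]
        [ 0    s_l  0  ]

where ``F`` is the mean number of eggs laid per adult female, ``s_e`` the
egg-to-larva survival probability and ``s_l`` the larva-to-adult survival
probability.  The characteristic polynomial is ``lambda^3 = F * s_e * s_l``,
so the per-step growth rate has the closed form ``(F s_e s_l)^(1/3)``.

A 3-cycle matrix is imprimitive (period 3): all three eigenvalues share the
modulus of the dominant root, so plain power iteration oscillates instead of
converging.  The dominant eigenvalue is therefore taken from a full
eigendecomposition (or the closed form), never from power iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VitalRates",
    "EigenAnalysis",
    "PerturbationAnalysis",
    "build_matrix",
    "lambda_closed_form",
    "eigen_analysis",
    "sensitivity_elasticity",
    "project",
]

STAGES = ("egg", "larva", "adult")

#: absolute tolerance for eigenpair validation and degeneracy checks
EIG_TOL = 1e-10


@dataclass(frozen=True)
class VitalRates:
    """Vital rates parameterizing one environment or treatment.

    Parameters
    ----------
    fecundity
        Eggs laid per adult female per generation (``F >= 0``).
    egg_survival
        Egg-to-larva survival probability (``0 <= s_e <= 1``).
    larval_survival
        Larva-to-adult survival probability (``0 <= s_l <= 1``).
    """

    fecundity: float
    egg_survival: float
    larval_survival: float

    def __post_init__(self) -> None:
        if not self.fecundity >= 0:
            raise ValueError(f"fecundity must be nonnegative, got {self.fecundity}")
        for name in ("egg_survival", "larval_survival"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.fecundity, self.egg_survival, self.larval_survival)


@dataclass(frozen=True)
class EigenAnalysis:
    """Perron eigen-analysis of a stage matrix.

    Attributes
    ----------
    lam
        Dominant eigenvalue: the asymptotic per-step population growth factor.
    r
        Log growth rate ``ln(lam)`` (``-inf`` when ``lam == 0``).
    w
        Stable stage distribution (right eigenvector, sums to 1).  NaN when
        the matrix is degenerate (``lam == 0``).
    v
        Stage reproductive values (left eigenvector, scaled so ``v @ w == 1``).
    spectrum_moduli
        Moduli of all eigenvalues, descending.  For a 3-cycle matrix all
        three equal ``lam`` (imprimitivity).
    degenerate
        True when ``lam == 0`` and the eigenvectors are undefined.
    """

    lam: float
    r: float
    w: np.ndarray
    v: np.ndarray
    spectrum_moduli: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class PerturbationAnalysis:
    """Sensitivities ``S_ij = d lambda / d a_ij`` and elasticities
    ``E_ij = (a_ij / lambda) S_ij`` of the dominant eigenvalue.

    Elasticities are masked to the structurally nonzero entries of the
    matrix and sum to 1 over them.
    """

    sensitivity: np.ndarray
    elasticity: np.ndarray


def build_matrix(vr: VitalRates) -> np.ndarray:
    """Build the 3-cycle stage projection matrix from vital rates.

    Entries: ``a[0, 2] = F``, ``a[1, 0] = s_e``, ``a[2, 1] = s_l``; all
    other entries are structurally zero (semelparity: no adult survival,
    no stage stasis).
    """
    A = np.zeros((3, 3))
    A[0, 2] = vr.fecundity
    A[1, 0] = vr.egg_survival
    A[2, 1] = vr.larval_survival
    return A


def lambda_closed_form(vr: VitalRates) -> float:
    """Dominant eigenvalue of the 3-cycle matrix, ``(F s_e s_l)^(1/3)``."""
    return float(np.cbrt(vr.fecundity * vr.egg_survival * vr.larval_survival))


def eigen_analysis(A: np.ndarray) -> EigenAnalysis:
    """Full eigen-analysis of a nonnegative stage matrix.

    Returns the Perron root (real, equal to the spectral radius), the stable
    stage distribution ``w`` (right eigenvector normalized to sum 1) and the
    reproductive values ``v`` (left eigenvector normalized so ``v @ w = 1``).

    A matrix whose dominant eigenvalue is (numerically) zero — e.g. zero
    fecundity, which makes the cycle matrix nilpotent — yields a flagged
    degenerate result with NaN eigenvectors rather than raising.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {A.shape}")
    if (A < 0).any():
        raise ValueError("stage matrix entries must be nonnegative")

    eigvals, right = np.linalg.eig(A)
    moduli = np.sort(np.abs(eigvals))[::-1]
    # For a nonnegative matrix the spectral radius is itself an eigenvalue
    # (real, nonnegative), so the eigenvalue of largest real part is the
    # Perron root.
    idx = int(np.argmax(eigvals.real))
    lam = float(eigvals[idx].real)

    if lam <= EIG_TOL:
        nan3 = np.full(3, np.nan)
        return EigenAnalysis(
            lam=0.0, r=-np.inf, w=nan3, v=nan3,
            spectrum_moduli=moduli, degenerate=True,
        )

    w = right[:, idx].real
    w = np.abs(w)  # Perron vector is sign-definite; fix orientation
    w = w / w.sum()

    lvals, left = np.linalg.eig(A.T)
    lidx = int(np.argmin(np.abs(lvals - lam)))
    v = np.abs(left[:, lidx].real)
    v = v / float(v @ w)

    return EigenAnalysis(
        lam=lam, r=float(np.log(lam)), w=w, v=v,
        spectrum_moduli=moduli, degenerate=False,
    )


def sensitivity_elasticity(A: np.ndarray, eig: EigenAnalysis | None = None) -> PerturbationAnalysis:
    """Sensitivity and elasticity of the dominant eigenvalue to each entry.

    Uses the eigenvector formula ``S_ij = v_i w_j / <v, w>``.  Elasticities
    are reported only for structurally nonzero entries; for the 3-cycle
    matrix each of the three arcs has elasticity exactly 1/3 (since
    ``ln lambda = (ln F + ln s_e + ln s_l) / 3``).
    """
    A = np.asarray(A, dtype=float)
    if eig is None:
        eig = eigen_analysis(A)
    if eig.degenerate or eig.lam <= 0:
        raise ValueError("elasticity is undefined for a degenerate (lambda = 0) matrix")
    S = np.outer(eig.v, eig.w) / float(eig.v @ eig.w)
    E = np.where(A > 0, (A / eig.lam) * S, 0.0)
    return PerturbationAnalysis(sensitivity=S, elasticity=E)


def project(A: np.ndarray, x0: np.ndarray, steps: int) -> np.ndarray:
    """Project stage abundances forward: ``x_{t+1} = A x_t``.

    Returns an array of shape ``(steps + 1, 3)`` containing the initial
    vector and every projected vector.
    """
    A = np.asarray(A, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (3,):
        raise ValueError(f"x0 must be a 3-vector, got shape {x0.shape}")
    if (x0 < 0).any():
        raise ValueError("stage abundances must be nonnegative")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    traj = np.empty((steps + 1, 3))
    traj[0] = x0
    for t in range(steps):
        traj[t + 1] = A @ traj[t]
    return traj
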