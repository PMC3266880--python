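"""Linear stability analysis for reaction-diffusion Turing instability.

The reaction system is linearized about its homogeneous steady state,
``du/dt = (A - mu_k * Dmat) u`` for each Laplacian eigenvalue
``mu_k = (k*pi/L)**2`` of the zero-flux 1-D domain.  Three conditions
classify diffusion-driven (Turing) instability of a quenched oscillator:

1. the oscillator-loop block A11 is unstable (the loop alone would
   oscillate);
2. the full reaction matrix A is stable (the quenching loop suppresses
   the oscillation in a well-mixed system);
3. some spatial mode k >= 1 makes ``A - mu_k * Dmat`` unstable
   (diffusion of the quench-loop species weakens the quench at high
   wave numbers and releases the oscillation).

All eigenvalue computations are numeric (``numpy.linalg.eigvals``);
real parts within a +/-1e-12 band of zero are flagged marginal rather
than silently classified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import model_core as mc

__all__ = [
    "LinearizedSystem",
    "TuringReport",
    "MARGINAL_BAND",
    "NEVER_UNSTABLE",
    "K_CAP",
    "jacobian",
    "laplacian_mu",
    "linearize",
    "leading_eigenvalue",
    "dispersion_relation",
    "instability_threshold",
    "min_unstable_k",
    "check_conditions",
]

MARGINAL_BAND = 1e-12     # |Re| below this is reported as marginal
K_CAP = 100               # default integer wave-number search cap
_MU_SCAN_CAP = 1e8        # D*mu bracket cap for the threshold bisection
NEVER_UNSTABLE = math.inf  # sentinel threshold when condition 1 fails


def laplacian_mu(L: float, k: int) -> float:
    """Eigenvalue ``mu_k = (k*pi/L)**2`` of -d²/dx² with zero-flux BCs."""
    if L <= 0:
        raise ValueError("L must be > 0")
    if not float(k).is_integer() or k < 0:
        raise ValueError("wave number k must be a non-negative integer")
    return (int(k) * math.pi / L) ** 2


def jacobian(model: str, params, state, *, warn_tol: float = 1e-6):
    """Analytic reaction Jacobian at ``state``; warns (via ``warnings``)
    if the state is not a steady state to ``warn_tol`` relative residual."""
    import warnings

    resid = mc.rates(model, state, params)
    vals = state.values if isinstance(state, mc.SpeciesState) else np.asarray(state)
    scale = max(1.0, float(np.max(np.abs(vals))))
    if np.max(np.abs(resid)) / scale > warn_tol:
        warnings.warn("jacobian evaluated away from a steady state",
                      RuntimeWarning, stacklevel=2)
    return mc.reaction_jacobian(model, state, params)


@dataclass
class LinearizedSystem:
    """Steady state, reaction Jacobian, diagonal diffusion matrix and
    domain length of one model instance."""

    steady_state: mc.SpeciesState
    A: np.ndarray
    D_diag: np.ndarray          # diagonal of Dmat, length²/time
    L: float
    osc_block: tuple            # index set of the oscillator-loop block
    diffuser_index: Optional[int] = None  # survives D = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.D_diag = np.asarray(self.D_diag, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.D_diag.shape != (n,):
            raise ValueError("diffusion diagonal must match A")
        if np.any(self.D_diag < 0):
            raise ValueError("diffusion coefficients must be >= 0")
        if self.L <= 0:
            raise ValueError("L must be > 0")

    @property
    def A11(self) -> np.ndarray:
        idx = np.asarray(self.osc_block, dtype=int)
        return self.A[np.ix_(idx, idx)]

    @property
    def diffuser(self) -> int:
        """Index of the single diffusible species."""
        nz = np.nonzero(self.D_diag)[0]
        if len(nz) == 1:
            return int(nz[0])
        if len(nz) == 0 and self.diffuser_index is not None:
            return int(self.diffuser_index)
        raise ValueError("expected exactly one diffusible species")

    @property
    def D(self) -> float:
        return float(self.D_diag[self.diffuser])


def linearize(model: str, params, state: Optional[mc.SpeciesState] = None,
              ) -> LinearizedSystem:
    """Steady state (found if not given) plus its linearization."""
    if state is None:
        state = mc.find_steady_state(model, params)
    A = mc.reaction_jacobian(model, state, params)
    mask = mc.diffusible_mask(model)
    return LinearizedSystem(
        steady_state=state,
        A=A,
        D_diag=mc.diffusion_coefficients(model, params),
        L=params.L,
        osc_block=mc.oscillator_block(model),
        diffuser_index=int(np.nonzero(mask)[0][0]),
    )


def leading_eigenvalue(M: np.ndarray) -> complex:
    """Eigenvalue of maximal real part (ties: larger |Im| first)."""
    ev = np.linalg.eigvals(M)
    return ev[np.lexsort((-np.abs(ev.imag), -ev.real))][0]


def dispersion_relation(lin: LinearizedSystem,
                        mu_grid: Sequence[float]) -> np.ndarray:
    """Leading eigenvalue of ``A - mu * Dmat`` for each mu >= 0."""
    mu_grid = np.asarray(mu_grid, dtype=float)
    if np.any(mu_grid < 0):
        raise ValueError("Laplacian eigenvalues must be >= 0")
    Dm = np.diag(lin.D_diag)
    return np.array([leading_eigenvalue(lin.A - mu * Dm) for mu in mu_grid])


def _lead_real_at_s(lin: LinearizedSystem, s: float) -> float:
    """Leading real part of A - s*E, where E has a unit entry at the
    diffuser diagonal; s is the product D*mu."""
    M = lin.A.copy()
    i = lin.diffuser
    M[i, i] -= s
    return leading_eigenvalue(M).real


def instability_threshold(lin: LinearizedSystem, *,
                          rel_tol: float = 1e-8) -> float:
    """Critical value of the product ``D * mu`` above which the spatial
    mode is unstable.

    Bisection on s = D*mu of the leading real part of ``A - s*E``.
    Returns 0.0 when the well-mixed system is already unstable
    (condition 2 fails) and the ``NEVER_UNSTABLE`` sentinel (inf) when
    no s up to the documented cap destabilizes the system (condition 1
    failing removes the high-s instability altogether).
    """
    if _lead_real_at_s(lin, 0.0) > MARGINAL_BAND:
        return 0.0
    # bracket: geometric scan for a sign change
    s_lo, f_lo = 0.0, _lead_real_at_s(lin, 0.0)
    s_hi = 1e-6 * max(1.0, np.max(np.abs(lin.A)))
    while s_hi <= _MU_SCAN_CAP:
        f_hi = _lead_real_at_s(lin, s_hi)
        if f_hi > 0.0:
            break
        s_lo, f_lo = s_hi, f_hi
        s_hi *= 2.0
    else:
        return NEVER_UNSTABLE
    while (s_hi - s_lo) > rel_tol * max(s_hi, 1e-300):
        mid = 0.5 * (s_lo + s_hi)
        if _lead_real_at_s(lin, mid) > 0.0:
            s_hi = mid
        else:
            s_lo = mid
    return 0.5 * (s_lo + s_hi)


def min_unstable_k(lin: LinearizedSystem, D: Optional[float] = None,
                   L: Optional[float] = None, *,
                   k_cap: int = K_CAP) -> float:
    """Smallest integer wave number k >= 1 whose mode is unstable
    (``D * mu_k`` above the instability threshold); ``inf`` if none up
    to ``k_cap``."""
    if D is None:
        D = lin.D_diag[lin.diffuser] if np.any(lin.D_diag > 0) else 0.0
    L = lin.L if L is None else L
    thr = instability_threshold(lin)
    if thr == 0.0:
        return 1
    if not np.isfinite(thr) or D == 0.0:
        return math.inf
    for k in range(1, k_cap + 1):
        if D * laplacian_mu(L, k) > thr:
            return k
    return math.inf


@dataclass
class TuringReport:
    """Outcome of the three instability conditions for one model."""

    condition1: bool
    condition2: bool
    condition3: bool
    lead_osc: complex            # leading eigenvalue of A11
    lead_full: complex           # leading eigenvalue of A
    lead_by_k: dict              # k -> leading eigenvalue of A - mu_k*Dmat
    threshold: float             # critical D*mu (0, finite, or inf)
    k_min: float                 # minimum unstable integer wave number
    marginal: bool               # any classification within the 1e-12 band
    mu_grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    lead_by_mu: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def turing(self) -> bool:
        return self.condition1 and self.condition2 and self.condition3

    def to_dict(self) -> dict:
        return {
            "condition1": self.condition1,
            "condition2": self.condition2,
            "condition3": self.condition3,
            "turing": self.turing,
            "lead_osc": [self.lead_osc.real, self.lead_osc.imag],
            "lead_full": [self.lead_full.real, self.lead_full.imag],
            "threshold_D_mu": (None if not np.isfinite(self.threshold)
                               else self.threshold),
            "k_min": None if not np.isfinite(self.k_min) else int(self.k_min),
            "marginal": self.marginal,
            "lead_by_k": {int(k): [v.real, v.imag]
                          for k, v in self.lead_by_k.items()},
        }


def check_conditions(lin: LinearizedSystem, D_scale: float = 1.0,
                     k_max: int = K_CAP, *,
                     mu_grid: Optional[Sequence[float]] = None,
                     ) -> TuringReport:
    """Evaluate the three Turing-instability conditions.

    ``D_scale`` multiplies the stored diffusion matrix (1.0 analyses the
    system as parameterized); ``k_max`` caps the integer wave-number
    search of condition 3.  An optional ``mu_grid`` attaches a sampled
    dispersion relation to the report.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    Dd = lin.D_diag * D_scale
    scaled = LinearizedSystem(lin.steady_state, lin.A, Dd, lin.L,
                              lin.osc_block)
    l_osc = leading_eigenvalue(lin.A11)
    l_full = leading_eigenvalue(lin.A)
    marginal = (abs(l_osc.real) < MARGINAL_BAND
                or abs(l_full.real) < MARGINAL_BAND)
    cond1 = bool(l_osc.real > 0.0)
    cond2 = bool(l_full.real < 0.0)

    Dm = np.diag(Dd)
    lead_by_k = {}
    cond3 = False
    for k in range(1, k_max + 1):
        mu = laplacian_mu(lin.L, k)
        lam = leading_eigenvalue(lin.A - mu * Dm)
        lead_by_k[k] = lam
        if abs(lam.real) < MARGINAL_BAND:
            marginal = True
        if lam.real > 0.0:
            cond3 = True
    marginal = bool(marginal)

    if np.any(Dd > 0):
        thr = instability_threshold(scaled)
        kmin = min_unstable_k(scaled, k_cap=k_max)
    else:
        thr, kmin = NEVER_UNSTABLE, math.inf

    rep = TuringReport(
        condition1=cond1, condition2=cond2, condition3=cond3,
        lead_osc=l_osc, lead_full=l_full, lead_by_k=lead_by_k,
        threshold=thr, k_min=kmin, marginal=marginal,
    )
    if mu_grid is not None:
        rep.mu_grid = np.asarray(mu_grid, dtype=float)
        rep.lead_by_mu = dispersion_relation(scaled, rep.mu_grid)
    return rep
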