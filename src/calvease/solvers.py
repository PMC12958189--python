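"""Outer threshold-model algorithms (Newton-Raphson, EM) over an inner PCG.

Both algorithms look for the joint mode of the threshold-model posterior,
and share the stationary condition Lambda theta = T' v(theta) (the
aggregate score equations), so at convergence they return the same
solutions.  They differ in the path:

* Newton-Raphson reweights: each outer round builds the weighted MME with
  expected-information weights w_i and working responses
  y_i = eta_i + v_i / w_i, so the equations change every round and the
  outer sequence converges quadratically near the mode.
* EM imputes: each outer round replaces the unobserved liability by its
  truncated-normal conditional mean and solves the *same* unit-weight MME
  with a new right-hand side; simple, but linearly convergent, so it needs
  far more outer rounds.

The inner solver is a Jacobi-preconditioned conjugate gradient, warm
started from the previous round so that inner error does not masquerade as
outer change.  "Inner iterations" reported are cumulative PCG iterations
across all outer rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .liability import Thresholds, em_imputed_liability, gf_score, gf_weight
from .model import DesignMatrices, MMESystem, VarianceComponents, assemble_mme

__all__ = [
    "SolverOptions",
    "SolveReport",
    "EvaluationResult",
    "SolverDivergence",
    "pcg_solve",
    "em_threshold_solve",
    "nr_threshold_solve",
]

log = logging.getLogger(__name__)


class SolverDivergence(RuntimeError):
    """Outer iteration diverged (relative solution change grew repeatedly)."""


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances and limits for the outer/inner iteration.

    outer_tol: stop when the relative solution change
        CD = ||theta_new - theta_old|| / ||theta_new|| falls below this.
    inner_tol: PCG relative-residual tolerance; kept far below outer_tol so
        the inner solve never limits outer convergence.
    damping: optional Newton step-halving when CD increases (overshoot guard).
    """

    outer_tol: float = 1e-6
    inner_tol: float = 1e-10
    max_outer: int = 1000
    max_inner: int = 10000
    damping: bool = False


@dataclass
class SolveReport:
    """Iteration accounting for one evaluation run."""

    solver: str
    outer: int = 0
    inner_total: int = 0
    final_cd: float = np.inf
    converged: bool = False
    rounds: list = field(default_factory=list)

    def log_round(self, cd: float, inner: int) -> None:
        self.outer += 1
        self.inner_total += inner
        self.final_cd = cd
        self.rounds.append({"round": self.outer, "cd": cd, "inner": inner})
        log.info("%s round %d: CD=%.3e inner=%d", self.solver, self.outer, cd, inner)


@dataclass
class EvaluationResult:
    """Partitioned solution vector of one run.

    ``gebv`` is (n_ped, 2): column 0 the sire-trait effect (SCE), column 1
    the maternal-trait effect (DCE; MGS effect under smgs, dam effect under
    smat).
    """

    ids: np.ndarray
    beta: np.ndarray
    hys: np.ndarray
    gebv: np.ndarray
    model: str
    solver: str

    def trait(self, which: str, animal_ids=None) -> np.ndarray:
        """SCE or DCE solutions, optionally for a list of external IDs."""
        col = {"sce": 0, "dce": 1}[which.lower()]
        v = self.gebv[:, col]
        if animal_ids is None:
            return v
        index = {a: i for i, a in enumerate(self.ids)}
        return np.array([v[index[a]] for a in animal_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.ids, "sce": self.gebv[:, 0], "dce": self.gebv[:, 1]}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def pcg_solve(
    a: sparse.spmatrix,
    rhs: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> tuple[np.ndarray, int]:
    """Jacobi-preconditioned conjugate gradient for a symmetric system.

    Stops when the relative residual ||r|| / ||rhs|| drops below ``tol``;
    returns (solution, iteration count).  On a singular but consistent
    system (fixed-effect nullspace) CG converges within the range space,
    yielding one member of the solution family.  Hitting ``max_iter``
    returns the partial solution with the count equal to max_iter.
    """
    rhs = np.asarray(rhs, float)
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm == 0.0:
        return np.zeros_like(rhs), 0
    diag = np.asarray(a.diagonal(), float)
    m_inv = np.where(diag > 0, 1.0 / np.where(diag > 0, diag, 1.0), 1.0)
    x = np.zeros_like(rhs) if start is None else np.array(start, float)
    r = rhs - a @ x
    if np.linalg.norm(r) / rhs_norm < tol:
        return x, 0
    z = m_inv * r
    p = z.copy()
    rz = r @ z
    for it in range(1, max_iter + 1):
        ap = a @ p
        pap = p @ ap
        if pap <= 0:
            # numerically null direction (singular system); stop cleanly
            return x, it
        alpha = rz / pap
        x += alpha * p
        r -= alpha * ap
        if np.linalg.norm(r) / rhs_norm < tol:
            return x, it
        z = m_inv * r
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x, max_iter


def _split_solution(
    theta: np.ndarray, system: MMESystem, model: str, solver: str
) -> EvaluationResult:
    b = system.blocking
    npd = system.design.n_ped
    gebv = np.column_stack([theta[b["sire"]], theta[b["maternal"]]])
    assert gebv.shape == (npd, 2)
    return EvaluationResult(
        ids=system.design.ped.ids,
        beta=theta[b["fixed"]],
        hys=theta[b["hys"]],
        gebv=gebv,
        model=model,
        solver=solver,
    )


def _outer_loop(system: MMESystem, t: Thresholds, opts: SolverOptions, solver: str):
    """Shared outer iteration driver; the per-round step is solver-specific."""
    scores = system.design.scores
    theta = np.zeros(system.n_equations)
    report = SolveReport(solver=solver)
    if solver == "em":
        coeff = system.coefficient(None)  # constant across rounds
    n_increase = 0
    prev_cd = np.inf
    for _ in range(opts.max_outer):
        eta = system.linear_predictor(theta)
        if solver == "em":
            y = em_imputed_liability(eta, scores, t)
            rhs = system.rhs(y)
        else:
            w = gf_weight(eta, t)
            v = gf_score(eta, scores, t)
            y = eta + v / w
            coeff = system.coefficient(w)
            rhs = system.rhs(y, w)
        theta_new, inner = pcg_solve(
            coeff, rhs, start=theta, tol=opts.inner_tol, max_iter=opts.max_inner
        )
        denom = np.linalg.norm(theta_new)
        cd = np.linalg.norm(theta_new - theta) / denom if denom > 0 else 0.0
        if opts.damping and cd > prev_cd:
            theta_new = 0.5 * (theta + theta_new)
            denom = np.linalg.norm(theta_new)
            cd = np.linalg.norm(theta_new - theta) / denom if denom > 0 else 0.0
        report.log_round(cd, inner)
        theta = theta_new
        if cd < opts.outer_tol:
            report.converged = True
            break
        n_increase = n_increase + 1 if cd > prev_cd else 0
        if n_increase >= 5:
            raise SolverDivergence(
                f"{solver} diverging: CD increased 5 consecutive rounds "
                f"(last CD={cd:.3e} at outer round {report.outer})"
            )
        prev_cd = cd
    return theta, report


def em_threshold_solve(
    design: DesignMatrices,
    vc: VarianceComponents,
    t: Thresholds,
    hinv=None,
    opts: SolverOptions = SolverOptions(),
) -> tuple[EvaluationResult, SolveReport]:
    """EM threshold solver: liability imputation with constant unit-weight MME.

    Each round imputes the unobserved liability of every record by its
    truncated-normal conditional mean given the current solutions and the
    observed category, then re-solves the linear MME with those
    pseudophenotypes on the right-hand side.
    """
    system = assemble_mme(design, vc, hinv)
    theta, report = _outer_loop(system, t, opts, "em")
    return _split_solution(theta, system, vc.model, "em"), report


def nr_threshold_solve(
    design: DesignMatrices,
    vc: VarianceComponents,
    t: Thresholds,
    hinv=None,
    opts: SolverOptions = SolverOptions(),
) -> tuple[EvaluationResult, SolveReport]:
    """Newton-Raphson threshold solver with expected-information weights.

    Each round rebuilds the MME from the normal scores: weights
    w_i = -E[d2 l_i / d eta^2] and working responses y_i = eta_i + v_i/w_i,
    then takes the Newton step by solving the weighted system.
    """
    system = assemble_mme(design, vc, hinv)
    theta, report = _outer_loop(system, t, opts, "nr")
    return _split_solution(theta, system, vc.model, "nr"), report
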