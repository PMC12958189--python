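"""End-to-end comparison pipeline: 4 runs (NR/EM x SMGS/SMAT) on one data set.

Mirrors the national comparison design: both model structures are fitted to
the same records with both solvers, and Pearson correlations among the four
runs' GEBV are tabulated separately for sire calving ease over phenotyped
sires and for daughter calving ease over phenotyped maternal grandsires,
alongside inner/outer iteration counts per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix, single_step_structure
from .liability import Thresholds
from .model import (
    RecordTable,
    SMGS_COMPONENTS,
    SMGS_THRESHOLDS,
    VarianceComponents,
    build_design,
    reparameterize_smgs_to_smat,
)
from .pedigree import PedigreeTable, a_inverse, extract_evaluation_pedigree
from .solvers import (
    EvaluationResult,
    SolveReport,
    SolverOptions,
    em_threshold_solve,
    nr_threshold_solve,
)

__all__ = [
    "ModelSpec",
    "ComparisonReport",
    "default_model_specs",
    "gebv_correlation",
    "run_single",
    "run_comparison",
]

log = logging.getLogger(__name__)


def gebv_correlation(
    res_a: EvaluationResult, res_b: EvaluationResult, ids, trait: str
) -> float:
    """Pearson correlation of one trait's GEBV between two runs over ``ids``.

    ``trait`` selects the solution block: 'sce' = sire effect, 'dce' =
    maternal effect.  IDs must be present in both results; zero variance in
    either vector is an error (correlation undefined).
    """
    ids = list(ids)
    if not ids:
        raise ValueError("empty id set")
    a = res_a.trait(trait, ids)
    b = res_b.trait(trait, ids)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError(f"zero variance in {trait} GEBV: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class ModelSpec:
    """Variance components and cutpoints used when fitting one structure."""

    vc: VarianceComponents
    thresholds: Thresholds


def default_model_specs() -> dict[str, ModelSpec]:
    """National parameter sets: printed SMGS estimates and their SMAT rescaling."""
    smat_vc, smat_t = reparameterize_smgs_to_smat(SMGS_COMPONENTS, SMGS_THRESHOLDS)
    return {
        "smgs": ModelSpec(vc=SMGS_COMPONENTS, thresholds=SMGS_THRESHOLDS),
        "smat": ModelSpec(vc=smat_vc, thresholds=smat_t),
    }


def run_single(
    records: RecordTable,
    full_ped: PedigreeTable,
    mode: str,
    solver: str,
    genos: GenotypeMatrix | None = None,
    spec: ModelSpec | None = None,
    opts: SolverOptions = SolverOptions(),
) -> tuple[EvaluationResult, SolveReport]:
    """One evaluation: extract the model's pedigree, assemble and solve."""
    spec = spec or default_model_specs()[mode]
    ped = extract_evaluation_pedigree(records, full_ped, mode)
    log.info("%s evaluation pedigree: %d animals", mode, len(ped))
    ainv = a_inverse(ped)
    use_genos = genos if genos is not None and genos.n_animals else None
    hinv = single_step_structure(ped, use_genos, ainv)
    design = build_design(records, ped, mode)
    solve = {"nr": nr_threshold_solve, "em": em_threshold_solve}[solver]
    return solve(design, spec.vc, spec.thresholds, hinv=hinv, opts=opts)


@dataclass
class ComparisonReport:
    """Correlation matrices and iteration accounting for the 4-run design."""

    labels: list
    sce: pd.DataFrame
    dce: pd.DataFrame
    reports: dict
    results: dict = field(default_factory=dict, repr=False)
    seed: int | None = None

    def iteration_table(self) -> pd.DataFrame:
        rows = [
            {
                "run": label,
                "outer": r.outer,
                "inner": r.inner_total,
                "converged": r.converged,
                "final_cd": r.final_cd,
            }
            for label, r in self.reports.items()
        ]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            "GEBV Pearson correlations, sire calving ease (phenotyped sires):",
            self.sce.round(4).to_string(),
            "",
            "GEBV Pearson correlations, daughter calving ease (phenotyped MGS):",
            self.dce.round(4).to_string(),
            "",
            "Iterations to convergence:",
            self.iteration_table().to_string(index=False),
        ]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.sce.to_csv(os.path.join(outdir, "sce_correlations.csv"))
        self.dce.to_csv(os.path.join(outdir, "dce_correlations.csv"))
        self.iteration_table().to_csv(
            os.path.join(outdir, "iterations.csv"), index=False
        )
        for label, res in self.results.items():
            res.write(os.path.join(outdir, f"solutions_{label}.csv"))
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(self.to_text() + "\n")


def run_comparison(
    records: RecordTable,
    full_ped: PedigreeTable,
    genos: GenotypeMatrix | None = None,
    specs: dict[str, ModelSpec] | None = None,
    opts: SolverOptions = SolverOptions(),
    models: tuple = ("smgs", "smat"),
    solvers: tuple = ("nr", "em"),
    seed: int | None = None,
) -> ComparisonReport:
    """Fit every solver x model combination and tabulate GEBV correlations.

    Non-converged runs keep their iteration report but are excluded from
    the correlation matrices (NaN cells).  Phenotyped sires / MGS are the
    animals appearing in the sire / MGS column of at least one record.
    """
    specs = specs or default_model_specs()
    results: dict[str, EvaluationResult] = {}
    reports: dict[str, SolveReport] = {}
    for mode in models:
        for solver in solvers:
            label = f"{solver}-{mode}"
            log.info("running %s", label)
            res, rep = run_single(
                records, full_ped, mode, solver, genos=genos,
                spec=specs[mode], opts=opts,
            )
            results[label] = res
            reports[label] = rep
            if not rep.converged:
                log.warning("%s did not converge (CD=%.3e)", label, rep.final_cd)
    labels = list(results)
    sires = records.phenotyped_sires()
    mgs = records.phenotyped_mgs()
    n = len(labels)
    sce = np.full((n, n), np.nan)
    dce = np.full((n, n), np.nan)
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if not (reports[la].converged and reports[lb].converged):
                continue
            sce[i, j] = gebv_correlation(results[la], results[lb], sires, "sce")
            dce[i, j] = gebv_correlation(results[la], results[lb], mgs, "dce")
    return ComparisonReport(
        labels=labels,
        sce=pd.DataFrame(sce, index=labels, columns=labels),
        dce=pd.DataFrame(dce, index=labels, columns=labels),
        reports=reports,
        results=results,
        seed=seed,
    )
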