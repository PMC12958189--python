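"""Record I/O, design matrices, variance components and MME assembly.

Two model structures share one phenotype.  Both attach the direct genetic
effect of a calving record to the service sire (the SCE trait); they differ
in where the maternal genetic effect (the DCE trait) lives:

* sire-maternal-grandsire (``smgs``): maternal effect on the MGS of the calf;
* sire-maternal (``smat``): maternal effect on the dam of the calf.

Liabilities follow

    lambda = X beta + Z_hys hys + Z_s s + Z_m m + e,    e ~ N(0, I)

with fixed effects year-season, breed x parity and breed x sex,
a random herd-year-season contemporary group, and the genetic pair (s, m)
distributed N(0, G0 kron H) where H combines pedigree and genomic
relationships.  The mixed-model equations assembled here are

    (T' W T + blockdiag(0, I/sigma2_hys, G0^-1 kron H^-1)) theta = T' W y

for T = [X | Z_hys | Z_s -> trait-1 block | Z_m -> trait-2 block]; the
solvers choose W and y (unit weights and imputed liabilities for EM,
information weights and working responses for Newton-Raphson).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .genomic import HInvStructure
from .liability import Thresholds
from .pedigree import PedigreeTable

__all__ = [
    "RecordTable",
    "VarianceComponents",
    "DesignMatrices",
    "MMESystem",
    "SMGS_COMPONENTS",
    "SMGS_THRESHOLDS",
    "read_records",
    "build_design",
    "reparameterize_smgs_to_smat",
    "assemble_mme",
]

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["sire", "dam", "mgs", "hys", "ys", "breed", "parity", "sex", "score"]
_UNKNOWN = {"0", "", "NA", "na", ".", "nan", "None"}


@dataclass
class RecordTable:
    """Validated calving records, one row per calving event.

    Columns: sire, dam, mgs (external IDs, "0" = unknown), hys (herd-year-
    season code), ys (year-season), breed, parity, sex, score (1..4).
    Calves themselves carry no ID; the record links the event to its sire
    and its dam or MGS.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def phenotyped_sires(self) -> np.ndarray:
        """Unique sires appearing in at least one record."""
        v = self.df["sire"].astype(str)
        return np.unique(v[~v.isin(_UNKNOWN)])

    def phenotyped_mgs(self) -> np.ndarray:
        """Unique animals appearing as MGS in at least one record."""
        v = self.df["mgs"].astype(str)
        return np.unique(v[~v.isin(_UNKNOWN)])

    def write(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_records(path) -> RecordTable:
    """Read delimited calving records; header with the canonical names required.

    Rows with a score outside 1..4 or with no sire are dropped with a
    counted warning.  A missing dam is fine when the MGS is present (SMGS
    evaluations) and vice versa; rows missing both maternal links are
    dropped.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    first = text.splitlines()[0] if text else ""
    sep = "," if "," in first else r"\s+"
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"records file missing column(s): {missing_cols}")
    df = df[RECORD_COLUMNS].copy()
    score = pd.to_numeric(df["score"], errors="coerce")
    ok = score.isin([1, 2, 3, 4])
    ok &= ~df["sire"].isin(_UNKNOWN)
    ok &= ~(df["dam"].isin(_UNKNOWN) & df["mgs"].isin(_UNKNOWN))
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(
            f"dropped {n_bad} record(s) with invalid score or missing sire/maternal link",
            stacklevel=2,
        )
    df = df[ok].copy()
    df["score"] = score[ok].astype(int)
    return RecordTable(df.reset_index(drop=True))


@dataclass(frozen=True)
class VarianceComponents:
    """Liability-scale (co)variance components for one model structure.

    ``sigma2_m`` / ``cov_sm`` refer to the maternal trait, i.e. the MGS
    effect under ``smgs`` and the dam effect under ``smat``.  The residual
    is fixed at 1 on the liability scale.
    """

    model: str  # "smgs" | "smat"
    sigma2_s: float
    cov_sm: float
    sigma2_m: float
    sigma2_hys: float
    sigma2_e: float = 1.0

    def __post_init__(self):
        if self.model not in ("smgs", "smat"):
            raise ValueError("model must be 'smgs' or 'smat'")
        if self.sigma2_hys <= 0:
            raise ValueError("sigma2_hys must be positive")
        # allow semidefinite G0 (degenerate reparameterization inputs);
        # inversion for MME assembly demands strict definiteness
        if np.any(linalg.eigvalsh(self.g0) < -1e-12):
            raise ValueError("genetic covariance matrix G0 is not positive semidefinite")

    @property
    def g0(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_s, self.cov_sm], [self.cov_sm, self.sigma2_m]], float
        )

    @property
    def g0_inv(self) -> np.ndarray:
        g0 = self.g0
        if np.any(linalg.eigvalsh(g0) <= 0):
            raise ValueError("G0 must be strictly positive definite to assemble MME")
        return linalg.inv(g0)


# national-evaluation estimates for the sire-MGS parameterization
SMGS_COMPONENTS = VarianceComponents(
    model="smgs", sigma2_s=0.0223, cov_sm=0.0113, sigma2_m=0.0224, sigma2_hys=0.216
)
SMGS_THRESHOLDS = Thresholds([-1.14, -0.63, 0.0])


def reparameterize_smgs_to_smat(
    vc: VarianceComponents, t: Thresholds
) -> tuple[VarianceComponents, Thresholds]:
    """Map sire-MGS components and cutpoints to the sire-dam (SMAT) scale.

    A maternal-grandsire effect carries half the dam's transmitting ability,
    so on the dam scale sigma2_d = 4 sigma2_mgs and cov_sd = 2 cov_s,mgs.
    The MGS parameterization leaves the other 3/4 of the maternal additive
    variance in the residual; removing it shrinks the residual to
    1 - 3 sigma2_mgs, and renormalizing the residual back to 1 multiplies
    every component by c = 1 / (1 - 3 sigma2_mgs).  The published national
    cutpoints follow the same factor c applied to the cutpoint vector
    (rather than sqrt(c)); this function reproduces the published numbers.
    """
    if vc.model != "smgs":
        raise ValueError("input components must be tagged 'smgs'")
    shrink = 1.0 - 3.0 * vc.sigma2_m
    if shrink <= 0:
        raise ValueError(
            "1 - 3*sigma2_mgs <= 0: MGS variance too large to renormalize"
        )
    c = 1.0 / shrink
    out = VarianceComponents(
        model="smat",
        sigma2_s=c * vc.sigma2_s,
        cov_sm=c * 2.0 * vc.cov_sm,
        sigma2_m=c * 4.0 * vc.sigma2_m,
        sigma2_hys=c * vc.sigma2_hys,
        sigma2_e=1.0,
    )
    return out, t.scaled(c)


@dataclass
class DesignMatrices:
    """Sparse incidence matrices plus the factor-level bookkeeping.

    The maternal incidence ``z_m`` points at the MGS (smgs) or the dam
    (smat); both genetic incidences index the same pedigree (trait blocks
    over identical animals).  ``record_rows`` maps design rows back to rows
    of the originating record table.
    """

    mode: str
    x: sparse.csr_matrix
    z_hys: sparse.csr_matrix
    z_s: sparse.csr_matrix
    z_m: sparse.csr_matrix
    scores: np.ndarray
    ped: PedigreeTable
    fixed_levels: dict
    hys_levels: np.ndarray
    record_rows: np.ndarray

    @property
    def n_records(self) -> int:
        return self.x.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.x.shape[1]

    @property
    def n_hys(self) -> int:
        return self.z_hys.shape[1]

    @property
    def n_ped(self) -> int:
        return len(self.ped)

    @property
    def n_equations(self) -> int:
        return self.n_fixed + self.n_hys + 2 * self.n_ped

    def t_matrix(self) -> sparse.csr_matrix:
        """Full record-to-equation incidence [X | Z_hys | Z_s | Z_m]."""
        return sparse.hstack(
            [self.x, self.z_hys, self.z_s, self.z_m], format="csr"
        )

    def blocking(self) -> dict:
        nf, nh, npd = self.n_fixed, self.n_hys, self.n_ped
        return {
            "fixed": slice(0, nf),
            "hys": slice(nf, nf + nh),
            "sire": slice(nf + nh, nf + nh + npd),
            "maternal": slice(nf + nh + npd, nf + nh + 2 * npd),
        }


def _onehot(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = codes.size
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def build_design(records: RecordTable, ped: PedigreeTable, mode: str) -> DesignMatrices:
    """Incidence matrices for one model structure over an indexed pedigree.

    Fixed-effect levels are the observed combinations of year-season,
    breed x parity and breed x sex.  Records whose sire or maternal link
    (MGS under smgs, dam under smat) is absent from the pedigree are
    dropped with a counted warning.  When both a dam and an MGS code are
    present and the pedigree knows the dam's sire, the pedigree wins and a
    mismatching record MGS is overridden (logged).
    """
    mode = mode.lower()
    if mode not in ("smgs", "smat"):
        raise ValueError("mode must be 'smgs' or 'smat'")
    df = records.df
    sire = df["sire"].astype(str).to_numpy()
    dam = df["dam"].astype(str).to_numpy()
    mgs = df["mgs"].astype(str).to_numpy()

    # MGS consistency: the pedigree sire of the dam overrides the record MGS
    resolved_mgs = mgs.copy()
    n_override = 0
    for i in range(len(df)):
        if dam[i] not in _UNKNOWN and ped.contains(dam[i]):
            ped_mgs_idx = ped.sire[ped._index[dam[i]]]
            if ped_mgs_idx >= 0:
                ped_mgs = str(ped.ids[ped_mgs_idx])
                if mgs[i] not in _UNKNOWN and mgs[i] != ped_mgs:
                    n_override += 1
                resolved_mgs[i] = ped_mgs
    if n_override:
        log.warning(
            "%d record MGS code(s) disagreed with the pedigree sire of the dam; "
            "pedigree taken",
            n_override,
        )

    maternal = resolved_mgs if mode == "smgs" else dam
    usable = np.array(
        [
            s not in _UNKNOWN and ped.contains(s)
            and m not in _UNKNOWN and ped.contains(m)
            for s, m in zip(sire, maternal)
        ]
    )
    n_drop = int((~usable).sum())
    if n_drop:
        warnings.warn(
            f"dropped {n_drop} record(s) with sire or maternal link not in pedigree",
            stacklevel=2,
        )
    rows = np.flatnonzero(usable)
    sub = df.iloc[rows]

    ys = sub["ys"].astype(str)
    bp = sub["breed"].astype(str) + "|" + sub["parity"].astype(str)
    bx = sub["breed"].astype(str) + "|" + sub["sex"].astype(str)
    blocks, levels = [], {}
    for name, fac in (("ys", ys), ("breed_parity", bp), ("breed_sex", bx)):
        codes, lvls = pd.factorize(fac)
        blocks.append(_onehot(codes, len(lvls)))
        levels[name] = np.asarray(lvls, dtype=object)
    x = sparse.hstack(blocks, format="csr")

    hys_codes, hys_lvls = pd.factorize(sub["hys"].astype(str))
    z_hys = _onehot(hys_codes, len(hys_lvls))

    n = rows.size
    npd = len(ped)
    z_s = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), ped.index_of(list(sire[rows])))), shape=(n, npd)
    )
    z_m = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), ped.index_of(list(maternal[rows])))), shape=(n, npd)
    )
    return DesignMatrices(
        mode=mode,
        x=x,
        z_hys=z_hys,
        z_s=z_s,
        z_m=z_m,
        scores=sub["score"].to_numpy(dtype=int),
        ped=ped,
        fixed_levels=levels,
        hys_levels=np.asarray(hys_lvls, dtype=object),
        record_rows=rows,
    )


@dataclass
class MMESystem:
    """One solving round's mixed-model equations in factored form.

    Holds the incidence T, the constant random-effect precision add-in
    Lambda (zero fixed block, I/sigma2_hys, G0^-1 kron H^-1), and the
    equation blocking.  ``coefficient(w)`` and ``rhs(w, y)`` build the
    round's system; with unit weights the coefficient never changes, which
    is what makes the EM solver's equations constant across rounds.
    """

    t: sparse.csr_matrix
    lam: sparse.csr_matrix
    blocking: dict
    design: DesignMatrices

    @property
    def n_equations(self) -> int:
        return self.t.shape[1]

    def coefficient(self, w: np.ndarray | None = None) -> sparse.csr_matrix:
        if w is None:
            twt = (self.t.T @ self.t).tocsr()
        else:
            tw = self.t.multiply(np.asarray(w)[:, None]).tocsr()
            twt = (self.t.T @ tw).tocsr()
        c = (twt + self.lam).tocsr()
        return c

    def rhs(self, y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
        y = np.asarray(y, float)
        if w is None:
            return self.t.T @ y
        return self.t.T @ (np.asarray(w) * y)

    def linear_predictor(self, theta: np.ndarray) -> np.ndarray:
        """Per-record eta = t_i' theta."""
        return self.t @ theta


def assemble_mme(
    design: DesignMatrices,
    vc: VarianceComponents,
    hinv: HInvStructure | None = None,
) -> MMESystem:
    """Build the factored MME for one model structure.

    The genetic precision couples each animal's sire-trait and maternal-
    trait equations through G0^-1 kron H^-1; without genotypes H^-1 is just
    the sparse pedigree A^-1.
    """
    if vc.model != design.mode:
        raise ValueError(
            f"variance components tagged {vc.model!r} but design is {design.mode!r}"
        )
    t = design.t_matrix()
    if hinv is None:
        from .pedigree import a_inverse

        h = a_inverse(design.ped)
    else:
        h = hinv.h_inverse()
    if h.shape[0] != design.n_ped:
        raise ValueError("H^-1 dimension does not match the design pedigree")
    gen_prec = sparse.kron(sparse.csr_matrix(vc.g0_inv), h, format="csr")
    lam = sparse.block_diag(
        [
            sparse.csr_matrix((design.n_fixed, design.n_fixed)),
            sparse.identity(design.n_hys, format="csr") / vc.sigma2_hys,
            gen_prec,
        ],
        format="csr",
    )
    return MMESystem(t=t, lam=lam, blocking=design.blocking(), design=design)
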