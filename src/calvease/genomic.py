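"""Genomic relationships and single-step H-inverse contributions.

The single-step evaluation replaces the pedigree relationship matrix A by a
matrix H that blends pedigree and genomic information.  Its inverse only
differs from A^-1 on the genotyped block:

    H^-1 = A^-1 + [0  0; 0  (G*)^-1 - (A22)^-1]

so this module produces exactly those two pieces: a dense correction block
indexed by the genotyped animals, kept separate from the sparse A^-1 so the
mixed-model assembly can add it to the right equations.

G is VanRaden's marker-based relationship matrix; before inversion it is
moment-matched (tuned) to A22 and blended with a small weight of A22 to
guarantee positive definiteness.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .pedigree import PedigreeTable, a_submatrix

__all__ = [
    "GenotypeMatrix",
    "HInvStructure",
    "read_genotypes",
    "vanraden_g",
    "blend_and_tune",
    "h_inverse_terms",
]

MAF_MIN = 0.01
DEFAULT_BLEND = 0.95  # weight of (tuned) G in the blended G*


@dataclass
class GenotypeMatrix:
    """Dosage matrix (animals x markers) with per-marker allele frequencies."""

    ids: np.ndarray
    dosages: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.frequencies is None:
            self.frequencies = self.dosages.mean(axis=0) / 2.0
        self.frequencies = np.asarray(self.frequencies, dtype=float)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def write(self, path) -> None:
        """Plain-matrix text: ID column then integer dosages, space separated."""
        df = pd.DataFrame(self.dosages.astype(int))
        df.insert(0, "ID", self.ids)
        df.to_csv(path, sep=" ", index=False)


@dataclass
class HInvStructure:
    """Sparse A^-1 over the pedigree plus the genotyped-block correction.

    ``correction`` is (G*)^-1 - (A22)^-1, a dense symmetric matrix over
    ``genotyped_idx`` (internal pedigree codes).  An empty index means plain
    pedigree BLUP.
    """

    a_inv: sparse.csr_matrix
    genotyped_idx: np.ndarray
    correction: np.ndarray

    def h_inverse(self) -> sparse.csr_matrix:
        """Assemble the full sparse H^-1 (A^-1 plus scattered correction)."""
        h = self.a_inv.tolil(copy=True)
        if self.genotyped_idx.size:
            ix = np.ix_(self.genotyped_idx, self.genotyped_idx)
            h[ix] = h[ix] + self.correction
        return h.tocsr()


def _parse_matrix_format(df: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    ids = df.iloc[:, 0].astype(str).to_numpy()
    return ids, df.iloc[:, 1:]


def _parse_raw_format(df: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    # PLINK .raw layout: FID IID PAT MAT SEX PHENOTYPE then one column per SNP
    meta = [c for c in df.columns[:6] if c.upper() in
            ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
    if "IID" not in [c.upper() for c in meta]:
        raise ValueError("raw-format genotype file lacks an IID column")
    iid_col = df.columns[[c.upper() for c in df.columns].index("IID")]
    ids = df[iid_col].astype(str).to_numpy()
    return ids, df.drop(columns=meta)


def read_frequencies(path) -> np.ndarray:
    """Per-marker allele frequencies from 2-column (marker, freq) text."""
    df = pd.read_csv(path, sep=r"[,\s]+", header=None, engine="python", comment="#")
    freqs = pd.to_numeric(df.iloc[:, -1], errors="coerce").to_numpy(dtype=float)
    if np.isnan(freqs).any() or np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("frequency file must hold values strictly in (0, 1)")
    return freqs


def read_genotypes(path, format: str = "matrix", frequency_path=None) -> GenotypeMatrix:
    """Read dosage genotypes from PLINK-RAW-like or plain-matrix text.

    Markers with minor allele frequency below 1% are dropped (count logged
    as a warning); missing entries (NA) are mean-imputed to twice the allele
    frequency.  Frequencies come from the sample unless a 2-column
    (marker, freq) file overrides them via ``frequency_path``.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    first = text.splitlines()[0] if text else ""
    sep = "," if "," in first else r"\s+"
    df = pd.read_csv(io.StringIO(text), sep=sep)
    if format == "raw":
        ids, dos = _parse_raw_format(df)
    elif format == "matrix":
        ids, dos = _parse_matrix_format(df)
    else:
        raise ValueError("format must be 'raw' or 'matrix'")
    m = dos.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~(np.isnan(m) | np.isin(m, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError(
            f"genotype file contains {int(bad.sum())} entries outside {{0,1,2,NA}}"
        )
    if np.isnan(m).all(axis=0).any():
        raise ValueError("genotype file contains an all-missing marker")
    n_na = int(np.isnan(m).sum())
    if frequency_path is not None:
        freqs = read_frequencies(frequency_path)
        if freqs.size != m.shape[1]:
            raise ValueError(
                f"frequency file has {freqs.size} entries for {m.shape[1]} markers"
            )
    else:
        freqs = np.nanmean(m, axis=0) / 2.0
    if n_na:
        warnings.warn(
            f"{n_na} missing genotype(s) imputed to twice the allele frequency",
            stacklevel=2,
        )
        nan_r, nan_c = np.nonzero(np.isnan(m))
        m[nan_r, nan_c] = 2.0 * freqs[nan_c]
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = maf >= MAF_MIN
    if (~keep).any():
        warnings.warn(
            f"dropped {int((~keep).sum())} marker(s) with MAF < {MAF_MIN}",
            stacklevel=2,
        )
    return GenotypeMatrix(ids=ids, dosages=m[:, keep], frequencies=freqs[keep])


def vanraden_g(genos: GenotypeMatrix, frequencies=None) -> np.ndarray:
    """Marker-based genomic relationship matrix G = ZZ' / (2 sum p(1-p)).

    Z centres the dosages at twice the allele frequency; by default the
    frequencies stored on the genotype matrix (computed from the sample
    unless a frequency file supplied them) are used.
    """
    if genos.n_animals < 2 or genos.n_markers < 1:
        raise ValueError("need at least 2 animals and 1 marker")
    p = np.asarray(frequencies if frequencies is not None else genos.frequencies)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers fixed: zero denominator in G")
    z = genos.dosages - 2.0 * p
    g = (z @ z.T) / denom
    return (g + g.T) / 2.0


def blend_and_tune(G: np.ndarray, A22: np.ndarray, blend: float = DEFAULT_BLEND) -> np.ndarray:
    """Tune G to the scale of A22, then blend: G* = w G_tuned + (1-w) A22.

    Tuning solves a + b*G for the two moment conditions
    mean(diag G*) = mean(diag A22) and mean(offdiag G*) = mean(offdiag A22),
    compensating for base-population allele-frequency mismatch; blending
    (default weight 0.95) guarantees an invertible G*.
    """
    G = np.asarray(G, float)
    A22 = np.asarray(A22, float)
    if G.shape != A22.shape or G.shape[0] != G.shape[1]:
        raise ValueError("G and A22 must be square and conformable")
    n = G.shape[0]
    off = ~np.eye(n, dtype=bool)
    md_g, mo_g = G.diagonal().mean(), G[off].mean() if n > 1 else 0.0
    md_a, mo_a = A22.diagonal().mean(), A22[off].mean() if n > 1 else 0.0
    if abs(md_g - mo_g) < 1e-12:
        raise ValueError("degenerate G: cannot moment-match (diag mean == offdiag mean)")
    b = (md_a - mo_a) / (md_g - mo_g)
    a = md_a - b * md_g
    g_star = blend * (a + b * G) + (1.0 - blend) * A22
    g_star = (g_star + g_star.T) / 2.0
    try:
        linalg.cholesky(g_star, lower=True)
    except linalg.LinAlgError:
        raise ValueError(
            "blended G* is not positive definite; increase the A22 blend weight"
        ) from None
    return g_star


def h_inverse_terms(
    a_inv: sparse.spmatrix,
    g_star: np.ndarray,
    a22: np.ndarray,
    genotyped_idx,
) -> HInvStructure:
    """Single-step correction block (G*)^-1 - (A22)^-1 over genotyped equations."""
    genotyped_idx = np.asarray(genotyped_idx, dtype=int)
    if genotyped_idx.size == 0:
        return HInvStructure(
            a_inv=sparse.csr_matrix(a_inv),
            genotyped_idx=genotyped_idx,
            correction=np.zeros((0, 0)),
        )
    g_star = np.asarray(g_star, float)
    a22 = np.asarray(a22, float)
    if g_star.shape != (genotyped_idx.size,) * 2 or a22.shape != g_star.shape:
        raise ValueError("G*, A22 and genotyped index set are not conformable")
    try:
        a22_inv = linalg.inv(linalg.cholesky(a22, lower=True))
        a22_inv = a22_inv.T @ a22_inv
    except linalg.LinAlgError:
        raise ValueError(
            "A22 is singular: duplicate genotyped animals or broken pedigree"
        ) from None
    gs_inv = linalg.inv(linalg.cholesky(g_star, lower=True))
    gs_inv = gs_inv.T @ gs_inv
    corr = gs_inv - a22_inv
    return HInvStructure(
        a_inv=sparse.csr_matrix(a_inv),
        genotyped_idx=genotyped_idx,
        correction=(corr + corr.T) / 2.0,
    )


def single_step_structure(
    ped: PedigreeTable,
    genos: GenotypeMatrix | None,
    a_inv: sparse.spmatrix,
    blend: float = DEFAULT_BLEND,
) -> HInvStructure:
    """Convenience pipeline: A22, VanRaden G, tune/blend, correction block.

    Genotyped animals absent from the evaluation pedigree are silently
    ignored (they carry no equations in this model).
    """
    if genos is None:
        return h_inverse_terms(a_inv, np.zeros((0, 0)), np.zeros((0, 0)), np.array([], int))
    in_ped = np.array([ped.contains(a) for a in genos.ids])
    if not in_ped.any():
        return h_inverse_terms(a_inv, np.zeros((0, 0)), np.zeros((0, 0)), np.array([], int))
    sub = GenotypeMatrix(
        ids=genos.ids[in_ped],
        dosages=genos.dosages[in_ped],
        frequencies=genos.frequencies,
    )
    a22 = a_submatrix(ped, list(sub.ids))
    g = vanraden_g(sub)
    g_star = blend_and_tune(g, a22, blend=blend)
    idx = ped.index_of(list(sub.ids))
    return h_inverse_terms(a_inv, g_star, a22, idx)
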