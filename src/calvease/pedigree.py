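"""Pedigree I/O, flag-and-trace extraction, inbreeding, A-inverse and A22.

External animal IDs are arbitrary strings; internally every pedigree is
renumbered to dense 0-based codes in topological order (parents before
offspring), the layout all matrices in the package use.  Unknown parents are
coded -1 internally ("0", "", "NA", "." or "na" in files) and are treated as
unrelated, non-inbred founders of the ordinary genetic base.

The numerator relationship matrix A itself is never formed at full scale:
the evaluation consumes its sparse inverse (Henderson's rules with
inbreeding from the Meuwissen-Luo algorithm) plus, for single-step, the
dense block A22 among genotyped animals computed by the tabular method on
that subset's ancestor closure (an explicitly O(n^2) desk-scale contract).
"""

from __future__ import annotations

import heapq
import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PedigreeTable",
    "PedigreeCycleError",
    "read_pedigree",
    "build_pedigree",
    "extract_evaluation_pedigree",
    "compute_inbreeding",
    "a_inverse",
    "a_submatrix",
    "tabular_a",
]

_UNKNOWN_CODES = {"0", "", "NA", "na", ".", "nan", "None"}


class PedigreeCycleError(ValueError):
    """Raised when an animal is (transitively) its own ancestor."""


@dataclass
class PedigreeTable:
    """Topologically sorted pedigree with dense internal codes.

    Attributes
    ----------
    ids : array of external ID strings, in topological order.
    sire, dam : int arrays of internal parent codes, -1 = unknown.
    f : inbreeding coefficients (filled by :func:`compute_inbreeding`,
        lazily computed on first access through :meth:`inbreeding`).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    f: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return self.ids.size

    def index_of(self, animal_ids) -> np.ndarray:
        """Internal codes for external IDs; raises KeyError on unknown ID."""
        if isinstance(animal_ids, str):
            animal_ids = [animal_ids]
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"animal {e.args[0]!r} not in pedigree") from None

    def contains(self, animal_id: str) -> bool:
        return animal_id in self._index

    def inbreeding(self) -> np.ndarray:
        if self.f is None:
            self.f = compute_inbreeding(self)
        return self.f

    def to_frame(self) -> pd.DataFrame:
        unk = np.array(["0"])
        sire_id = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], unk)
        dam_id = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], unk)
        return pd.DataFrame({"animal": self.ids, "sire": sire_id, "dam": dam_id})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_renumber_map(self, path) -> None:
        """Persist the external-ID -> 1-based internal code map as 2-column text."""
        pd.DataFrame({"animal": self.ids, "code": np.arange(len(self)) + 1}).to_csv(
            path, index=False, sep=" ", header=False
        )


def _toposort(ids, sire_ext, dam_ext):
    """Kahn's algorithm over the parent->offspring DAG; deterministic order.

    Returns the ids in an order where every parent precedes its offspring,
    or raises PedigreeCycleError naming one cycle.
    """
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i, (s, d) in enumerate(zip(sire_ext, dam_ext)):
        for p in (s, d):
            if p is not None:
                j = pos[p]
                children[j].append(i)
                indeg[i] += 1
    order = []
    ready = sorted(np.flatnonzero(indeg == 0).tolist())
    head = 0
    ready = list(ready)
    while head < len(ready):
        i = ready[head]
        head += 1
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) != n:
        stuck = [ids[i] for i in np.flatnonzero(indeg > 0)]
        raise PedigreeCycleError(
            f"pedigree contains a cycle involving: {', '.join(map(str, stuck[:10]))}"
        )
    return order


def build_pedigree(animal, sire, dam) -> PedigreeTable:
    """Validate and topologically sort a pedigree given as three ID sequences.

    Parents that never appear in the animal column are auto-appended as
    founders with a warning; duplicate animal rows are rejected.
    """
    animal = [str(a) for a in animal]
    sire = [None if str(s) in _UNKNOWN_CODES else str(s) for s in sire]
    dam = [None if str(d) in _UNKNOWN_CODES else str(d) for d in dam]
    seen = set()
    for a in animal:
        if a in seen:
            raise ValueError(f"duplicate pedigree row for animal {a!r}")
        seen.add(a)
    for a, s, d in zip(animal, sire, dam):
        if a == s or a == d:
            raise PedigreeCycleError(f"animal {a!r} listed as its own parent")
    missing = []
    for plist in (sire, dam):
        for p in plist:
            if p is not None and p not in seen:
                missing.append(p)
                seen.add(p)
    if missing:
        warnings.warn(
            f"{len(missing)} parent(s) not listed as animals; appended as founders",
            stacklevel=2,
        )
        animal = animal + missing
        sire = sire + [None] * len(missing)
        dam = dam + [None] * len(missing)
    order = _toposort(animal, sire, dam)
    ids = np.array([animal[i] for i in order], dtype=object)
    index = {a: i for i, a in enumerate(ids)}
    sire_idx = np.array(
        [index[sire[i]] if sire[i] is not None else -1 for i in order], dtype=int
    )
    dam_idx = np.array(
        [index[dam[i]] if dam[i] is not None else -1 for i in order], dtype=int
    )
    return PedigreeTable(ids=ids, sire=sire_idx, dam=dam_idx)


def _sniff_delim(first_line: str) -> str | None:
    return "," if "," in first_line else None  # None -> any whitespace


def read_pedigree(path) -> PedigreeTable:
    """Read a 3-column (animal, sire, dam) delimited text pedigree.

    Comma or whitespace delimited (auto-detected); an optional header row is
    recognised by the token 'animal', 'id', or 'sire' in the first line.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return PedigreeTable(
            ids=np.array([], dtype=object),
            sire=np.array([], dtype=int),
            dam=np.array([], dtype=int),
        )
    delim = _sniff_delim(lines[0])
    first = [tok.strip().lower() for tok in lines[0].replace(",", " ").split()]
    has_header = bool({"animal", "id", "sire", "dam"} & set(first))
    df = pd.read_csv(
        io.StringIO("\n".join(lines)),
        sep=delim if delim else r"\s+",
        header=0 if has_header else None,
        dtype=str,
        keep_default_na=False,
    )
    if df.shape[1] < 3:
        raise ValueError("pedigree file needs 3 columns: animal, sire, dam")
    cols = df.columns[:3]
    return build_pedigree(df[cols[0]], df[cols[1]], df[cols[2]])


def extract_evaluation_pedigree(records, full_ped: PedigreeTable, mode: str) -> PedigreeTable:
    """Flag-and-trace pruning of the full pedigree for one model structure.

    Flags all sires plus either all maternal grandsires (``mode='smgs'``) or
    all dams (``mode='smat'``) appearing in the records, then traces back
    every ancestor of a flagged animal.  The result is the minimal
    ancestor-closed sub-pedigree containing the flagged set.
    """
    mode = mode.lower()
    if mode not in ("smgs", "smat"):
        raise ValueError("mode must be 'smgs' or 'smat'")
    df = records.df if hasattr(records, "df") else records
    maternal_col = "mgs" if mode == "smgs" else "dam"
    flagged = set()
    for col in ("sire", maternal_col):
        vals = df[col].astype(str) if len(df) else []
        flagged.update(v for v in vals if v not in _UNKNOWN_CODES)
    keep = np.zeros(len(full_ped), dtype=bool)
    present = [full_ped._index[a] for a in flagged if full_ped.contains(a)]
    missing = len(flagged) - len(present)
    if missing:
        warnings.warn(
            f"{missing} flagged animal(s) absent from the full pedigree; "
            "they will be added as founders",
            stacklevel=2,
        )
    keep[present] = True
    # ancestors precede descendants, so one reverse sweep closes the set
    for i in range(len(full_ped) - 1, -1, -1):
        if keep[i]:
            for p in (full_ped.sire[i], full_ped.dam[i]):
                if p >= 0:
                    keep[p] = True
    kept = np.flatnonzero(keep)
    ids = full_ped.ids[kept]
    absent = sorted(a for a in flagged if not full_ped.contains(a))
    animal = list(ids) + absent
    sire_ext = [
        full_ped.ids[full_ped.sire[i]] if full_ped.sire[i] >= 0 else None for i in kept
    ] + [None] * len(absent)
    dam_ext = [
        full_ped.ids[full_ped.dam[i]] if full_ped.dam[i] >= 0 else None for i in kept
    ] + [None] * len(absent)
    return build_pedigree(animal, sire_ext, dam_ext)


def compute_inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Exact inbreeding coefficients by the Meuwissen-Luo algorithm.

    Walks each animal's ancestor list accumulating L (the Cholesky rows of A)
    and the Mendelian-sampling variances; founders get F = 0.  O(n * depth^2)
    but comfortably fast at the pedigree sizes this package targets.
    """
    n = len(ped)
    f = np.zeros(n)
    d = np.zeros(n)  # Mendelian sampling variance per animal
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        fs = f[sire[i]] if sire[i] >= 0 else -1.0
        fd = f[dam[i]] if dam[i] >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if sire[i] < 0 or dam[i] < 0:
            f[i] = 0.0
            continue
        # accumulate a_ii = sum_j L_ij^2 d_j over the ancestor list of i,
        # visiting ancestors in decreasing code order via a lazy max-heap
        L = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue  # already visited through a duplicate heap entry
            aii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in L:
                        heapq.heappush(heap, -p)
                        L[p] = 0.0
                    L[p] += 0.5 * lj
        f[i] = aii - 1.0
    return f


def a_inverse(ped: PedigreeTable) -> sparse.csr_matrix:
    """Sparse inverse of the numerator relationship matrix A.

    Henderson's rules with Mendelian-sampling variances adjusted for
    parental inbreeding: for animal i with parents s, d the contribution is
    alpha_i * [1, -0.5, -0.5]' [1, -0.5, -0.5] on (i, s, d), where
    alpha_i = 1 / (0.5 - 0.25 (F_s + F_d)) and a missing parent contributes
    F = -1 to the variance and drops out of the outer product.
    """
    n = len(ped)
    f = ped.inbreeding()
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[d] if d >= 0 else -1.0
        alpha = 1.0 / (0.5 - 0.25 * (fs + fd))
        members = [(i, 1.0)] + [(p, -0.5) for p in (s, d) if p >= 0]
        for a, ca in members:
            for b, cb in members:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * ca * cb)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n, n), dtype=float
    )


def tabular_a(ped: PedigreeTable) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (O(n^2))."""
    n = len(ped)
    f = ped.inbreeding()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * A[s]
        if d >= 0:
            row += 0.5 * A[d]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        A[i, i] = 1.0 + f[i]
    return A


def a_submatrix(ped: PedigreeTable, subset_ids) -> np.ndarray:
    """Exact relationship block among ``subset_ids`` (external IDs).

    Computed by the tabular method on the subset's ancestor closure, then
    restricted; quadratic in the closure size, intended for the genotyped
    subset of desk-scale evaluations.
    """
    idx = ped.index_of(subset_ids)
    keep = np.zeros(len(ped), dtype=bool)
    keep[idx] = True
    for i in range(len(ped) - 1, -1, -1):
        if keep[i]:
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    keep[p] = True
    closure = np.flatnonzero(keep)
    remap = -np.ones(len(ped), dtype=int)
    remap[closure] = np.arange(closure.size)
    sub = PedigreeTable(
        ids=ped.ids[closure],
        sire=np.where(ped.sire[closure] >= 0, remap[np.maximum(ped.sire[closure], 0)], -1),
        dam=np.where(ped.dam[closure] >= 0, remap[np.maximum(ped.dam[closure], 0)], -1),
    )
    A = tabular_a(sub)
    pos = remap[idx]
    return A[np.ix_(pos, pos)]
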