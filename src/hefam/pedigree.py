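"""Pedigree parsing and pedigree-derived covariance structure.

The family covariance model used throughout this package decomposes the
phenotypic covariance of related individuals into three matrices built
purely from pedigree records:

* ``A`` — the additive (numerator) relationship matrix, twice the kinship
  matrix ``Phi``.  ``Phi_ij`` is the probability that an allele drawn at
  random from individual *i* is identical by descent to one drawn from *j*.
* ``H`` — the shared-household matrix, 1 for pairs of siblings raised in the
  same household (and on the diagonal), 0 elsewhere.
* ``I`` — the identity, carrying the residual variance.

Both ``A`` and ``H`` are block diagonal by family, which downstream model
fitting exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "PedigreeTable",
    "CovarianceStructure",
    "read_pedigree",
    "kinship_matrix",
    "relationship_matrix",
    "household_matrix",
    "covariance_structure",
]

MISSING_PARENT_CODES = {"0", "", "na", "nan", "none", "-9"}
SEX_CODES = {"1": "male", "2": "female", "m": "male", "f": "female",
             "male": "male", "female": "female"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, bad codes)."""


@dataclass
class PedigreeTable:
    """Validated pedigree: one row per individual.

    ``table`` columns: ``individual_id``, ``father_id``, ``mother_id``
    (``None`` for founders), ``sex`` ("male"/"female"), ``family_id``,
    ``household_id`` (``None`` allowed), ``status`` ("case"/"control"/None),
    ``synthetic_founder`` (bool flag for parents invented to complete
    single-parent records).
    """

    table: pd.DataFrame
    n_synthetic_founders: int = 0

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        _validate(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["individual_id"])

    def __len__(self) -> int:
        return len(self.table)

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for iid, fam in zip(self.table["individual_id"], self.table["family_id"]):
            out.setdefault(fam, []).append(iid)
        return out


def _normalise_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s.lower() in MISSING_PARENT_CODES else s


def _normalise_sex(value) -> str:
    s = str(value).strip().lower()
    if s not in SEX_CODES:
        raise PedigreeError(f"unknown sex code: {value!r}")
    return SEX_CODES[s]


def _validate(tab: pd.DataFrame) -> None:
    ids = tab["individual_id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicate individual_id: {sorted(set(dup))}")
    known = set(ids)
    fam = dict(zip(tab["individual_id"], tab["family_id"]))
    for _, row in tab.iterrows():
        for p in (row["father_id"], row["mother_id"]):
            if p is not None:
                if p not in known:
                    raise PedigreeError(f"parent {p!r} of {row['individual_id']!r} not in table")
                if fam[p] != row["family_id"]:
                    raise PedigreeError(
                        f"parent {p!r} and child {row['individual_id']!r} in different families")
    _topological_order(tab)  # raises on cycles


def _topological_order(tab: pd.DataFrame) -> list[str]:
    """Order ids so parents precede children; raise PedigreeError on a cycle."""
    parents = {
        r["individual_id"]: [p for p in (r["father_id"], r["mother_id"]) if p is not None]
        for _, r in tab.iterrows()
    }
    order: list[str] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    for start in parents:
        if start in state:
            continue
        stack = [(start, iter(parents[start]))]
        state[start] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if state.get(p) == 0:
                    raise PedigreeError(f"pedigree cycle involving {p!r}")
                if p not in state:
                    state[p] = 0
                    stack.append((p, iter(parents[p])))
                    advanced = True
                    break
            if not advanced:
                state[node] = 1
                order.append(node)
                stack.pop()
    return order


def read_pedigree(path) -> PedigreeTable:
    """Read a whitespace-delimited pedigree file.

    Column order follows PLINK ``.fam``: family, individual, father, mother,
    sex (1=male, 2=female), phenotype/status, plus an optional seventh
    household column.  Missing parents are coded ``0`` or empty.  Individuals
    with exactly one known parent (or referencing an absent parent) have the
    missing parent completed by a flagged synthetic founder.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedigreeError(f"expected >=5 whitespace-delimited columns: {line!r}")
            fields += [None] * (7 - len(fields))
            fam, iid, pat, mat, sex, status, household = fields[:7]
            rows.append({
                "individual_id": iid,
                "father_id": _normalise_parent(pat),
                "mother_id": _normalise_parent(mat),
                "sex": _normalise_sex(sex),
                "family_id": fam,
                "household_id": _normalise_parent(household),
                "status": _decode_status(status),
                "synthetic_founder": False,
            })
    tab = pd.DataFrame(rows)
    tab, n_added = _complete_founders(tab)
    return PedigreeTable(tab, n_synthetic_founders=n_added)


def _decode_status(value) -> str | None:
    s = _normalise_parent(value)
    if s is None:
        return None
    return {"1": "control", "2": "case", "case": "case", "control": "control"}.get(s.lower(), None)


def _complete_founders(tab: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    known = set(tab["individual_id"])
    extra = []
    counter = 0
    for idx, row in tab.iterrows():
        f, m = row["father_id"], row["mother_id"]
        need = []
        if (f is None) != (m is None):
            need.append("father" if f is None else "mother")
        for which, pid in (("father", f), ("mother", m)):
            if pid is not None and pid not in known:
                known.add(pid)
                extra.append({
                    "individual_id": pid,
                    "father_id": None, "mother_id": None,
                    "sex": "male" if which == "father" else "female",
                    "family_id": row["family_id"], "household_id": None,
                    "status": None, "synthetic_founder": True,
                })
        for which in need:
            counter += 1
            pid = f"_founder{counter}"
            while pid in known:
                counter += 1
                pid = f"_founder{counter}"
            known.add(pid)
            tab.at[idx, f"{which}_id"] = pid
            extra.append({
                "individual_id": pid,
                "father_id": None, "mother_id": None,
                "sex": "male" if which == "father" else "female",
                "family_id": row["family_id"], "household_id": None,
                "status": None, "synthetic_founder": True,
            })
    n_added = len(extra)
    if extra:
        tab = pd.concat([tab, pd.DataFrame(extra)], ignore_index=True)
    return tab, n_added


def kinship_matrix(ped: PedigreeTable) -> pd.DataFrame:
    """Kinship matrix ``Phi`` by the standard tabular recursion.

    ``Phi_ii = 0.5 * (1 + Phi_fm)`` for an individual with parents f, m
    (0.5 for a non-inbred founder) and ``Phi_ij = 0.5 * (Phi_fj + Phi_mj)``,
    evaluated with parents before children.  Handles inbreeding.
    """
    tab = ped.table
    order = _topological_order(tab)
    ids = ped.ids
    pos = {iid: k for k, iid in enumerate(ids)}
    father = dict(zip(tab["individual_id"], tab["father_id"]))
    mother = dict(zip(tab["individual_id"], tab["mother_id"]))
    n = len(ids)
    phi = np.zeros((n, n))
    done: list[str] = []
    for iid in order:
        i = pos[iid]
        f, m = father[iid], mother[iid]
        if f is None and m is None:
            phi[i, i] = 0.5
        else:
            # completion guarantees both parents present here
            phi[i, i] = 0.5 * (1.0 + phi[pos[f], pos[m]])
        for jid in done:
            j = pos[jid]
            if f is None and m is None:
                val = 0.0
            else:
                val = 0.5 * (phi[pos[f], j] + phi[pos[m], j])
            phi[i, j] = phi[j, i] = val
        done.append(iid)
    return pd.DataFrame(phi, index=ids, columns=ids)


def relationship_matrix(phi: pd.DataFrame) -> pd.DataFrame:
    """Additive relationship matrix ``A = 2 * Phi``."""
    return 2.0 * phi


def household_matrix(ped: PedigreeTable, include_half_sibs: bool = False) -> pd.DataFrame:
    """Shared-environment matrix ``H``.

    ``h_ij = 1`` iff i == j, or i and j are siblings sharing the same
    non-missing ``household_id``.  "Siblings" means full siblings by
    default; set ``include_half_sibs`` to also count pairs sharing a single
    parent.  Missing household ids are treated as unshared.
    """
    tab = ped.table
    ids = ped.ids
    n = len(ids)
    father = tab["father_id"].to_numpy(object)
    mother = tab["mother_id"].to_numpy(object)
    house = tab["household_id"].to_numpy(object)
    H = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if house[i] is None or house[i] != house[j]:
                continue
            same_f = father[i] is not None and father[i] == father[j]
            same_m = mother[i] is not None and mother[i] == mother[j]
            sib = (same_f and same_m) if not include_half_sibs else (same_f or same_m)
            if sib:
                H[i, j] = H[j, i] = 1.0
    return pd.DataFrame(H, index=ids, columns=ids)


@dataclass
class CovarianceStructure:
    """Ordered individuals with their A, H matrices and family membership."""

    ids: list[str]
    A: np.ndarray
    H: np.ndarray
    family_incidence: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        n = len(self.ids)
        if self.A.shape != (n, n) or self.H.shape != (n, n):
            raise ValueError("matrix dimensions do not match id list")

    @property
    def n(self) -> int:
        return len(self.ids)

    def family_blocks(self) -> list[np.ndarray]:
        """Index arrays, one per family, covering all individuals."""
        groups: dict[str, list[int]] = {}
        for k, iid in enumerate(self.ids):
            groups.setdefault(self.family_incidence[iid], []).append(k)
        return [np.asarray(v) for v in groups.values()]

    def subset(self, keep_ids: list[str]) -> "CovarianceStructure":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = np.asarray([pos[i] for i in keep_ids])
        return CovarianceStructure(
            ids=list(keep_ids),
            A=self.A[np.ix_(idx, idx)],
            H=self.H[np.ix_(idx, idx)],
            family_incidence={i: self.family_incidence[i] for i in keep_ids},
        )


def covariance_structure(ped: PedigreeTable, include_half_sibs: bool = False) -> CovarianceStructure:
    """Build A, H and the family-incidence map from a pedigree."""
    phi = kinship_matrix(ped)
    A = relationship_matrix(phi)
    H = household_matrix(ped, include_half_sibs=include_half_sibs)
    fam = dict(zip(ped.table["individual_id"], ped.table["family_id"]))
    return CovarianceStructure(ids=ped.ids, A=A.to_numpy(), H=H.to_numpy(), family_incidence=fam)
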