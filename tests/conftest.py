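import numpy as np
import pandas as pd
import pytest

from hefam.pedigree import PedigreeTable


def make_pedigree(rows):
    """Rows: (iid, father, mother, sex, fam, household)."""
    return PedigreeTable(pd.DataFrame([
        {"individual_id": r[0], "father_id": r[1], "mother_id": r[2],
         "sex": r[3], "family_id": r[4], "household_id": r[5],
         "status": "control", "synthetic_founder": False}
        for r in rows
    ]))


@pytest.fixture
def trio():
    return make_pedigree([
        ("dad", None, None, "male", "f1", None),
        ("mum", None, None, "female", "f1", None),
        ("kid", "dad", "mum", "male", "f1", "h1"),
    ])


@pytest.fixture
def nuclear():
    """Two founders, three full sibs in one household."""
    return make_pedigree([
        ("p1", None, None, "male", "f1", None),
        ("p2", None, None, "female", "f1", None),
        ("s1", "p1", "p2", "male", "f1", "h1"),
        ("s2", "p1", "p2", "female", "f1", "h1"),
        ("s3", "p1", "p2", "male", "f1", "h2"),
    ])


def random_pedigree(rng, n_members=10, fam="f1"):
    """Random valid pedigree grown by repeatedly mating existing members."""
    rows = [("i1", None, None, "male", fam, None),
            ("i2", None, None, "female", fam, None)]
    males, females = ["i1"], ["i2"]
    for k in range(3, n_members + 1):
        iid = f"i{k}"
        sex = "male" if rng.random() < 0.5 else "female"
        if rng.random() < 0.35 or len(males) == 0 or len(females) == 0:
            rows.append((iid, None, None, sex, fam, None))
        else:
            f = males[int(rng.integers(len(males)))]
            m = females[int(rng.integers(len(females)))]
            rows.append((iid, f, m, sex, fam, f"h_{f}_{m}"))
        (males if sex == "male" else females).append(iid)
    return make_pedigree(rows)


def gene_drop_kinship(ped, n_drops, seed):
    """Monte-Carlo kinship oracle: label founder alleles uniquely, drop them
    down the pedigree, and estimate Phi_ij as the probability that a random
    allele from i matches a random allele from j (average over the 4 pairs)."""
    from hefam.pedigree import _topological_order
    rng = np.random.default_rng(seed)
    tab = ped.table
    ids = ped.ids
    pos = {iid: k for k, iid in enumerate(ids)}
    order = _topological_order(tab)
    father = dict(zip(tab["individual_id"], tab["father_id"]))
    mother = dict(zip(tab["individual_id"], tab["mother_id"]))
    n = len(ids)
    alleles = np.zeros((n_drops, n, 2), dtype=np.int32)
    label = 0
    for iid in order:
        i = pos[iid]
        f, m = father[iid], mother[iid]
        if f is None:
            alleles[:, i, 0] = label
            alleles[:, i, 1] = label + 1
            label += 2
        else:
            pf = rng.integers(2, size=n_drops)
            pm = rng.integers(2, size=n_drops)
            r = np.arange(n_drops)
            alleles[:, i, 0] = alleles[r, pos[f], pf]
            alleles[:, i, 1] = alleles[r, pos[m], pm]
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ai, aj = alleles[:, i, :], alleles[:, j, :]
            match = sum((ai[:, a] == aj[:, b]).mean() for a in range(2) for b in range(2))
            if i == j:
                # self-kinship: draw two alleles with replacement
                phi[i, i] = match / 4.0
            else:
                phi[i, j] = phi[j, i] = match / 4.0
    return pd.DataFrame(phi, index=ids, columns=ids)
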