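"""Synthetic family data: pedigrees, gene-dropped genotypes, phenotypes.

The generator emulates the structure of a family study of plasma protein
levels: ~20 extended three-generation pedigrees of 6-26 members each,
standardized quantitative traits built from fixed effects (sex, disease
status), an additive-genetic component with covariance ``s2G * A``, a
shared-household component ``s2C * H``, and iid residual noise, plus
biallelic SNPs dropped through the pedigree at given minor allele
frequencies with optional planted additive effects.

Variances are on the unit-total scale: ``s2G = h2_true``,
``s2C = c2_true`` and the residual picks up the remainder after any
planted SNP variance ``sum(2 p (1-p) beta^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import CovarianceStructure, PedigreeTable, covariance_structure

__all__ = [
    "SimulationConfig",
    "GenotypeTable",
    "simulate_pedigree",
    "add_singletons",
    "gene_drop",
    "simulate_phenotype",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated study design: 20 extended families of
    6-26 members, sex and disease status as standardized fixed effects,
    and MAFs drawn uniformly on [0.05, 0.5].
    """

    n_families: int = 20
    family_sizes: tuple[int, int] = (6, 26)
    h2_true: float = 0.6
    c2_true: float = 0.1
    beta_sex: float = 0.2
    beta_ms: float = 0.2
    ms_prevalence_in_families: float = 0.2
    n_snps: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_effects: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.h2_true <= 1 and 0 <= self.c2_true <= 1):
            raise ValueError("h2_true and c2_true must lie in [0, 1]")
        if self.h2_true + self.c2_true > 1:
            raise ValueError("h2_true + c2_true must be <= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must sit inside (0, 0.5]")


@dataclass
class GenotypeTable:
    """Biallelic SNP dosages for an ordered set of individuals.

    ``snps`` has one row per SNP (snp_id, chromosome, position,
    effect_allele, reference_allele); ``dosages`` is individuals x SNPs
    with values in {0, 1, 2} (NaN for missing), counting effect alleles.
    """

    ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snps)):
            raise ValueError("dosage matrix shape does not match ids x snps")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def maf(self) -> np.ndarray:
        """Per-SNP frequency of the effect allele among non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_snps(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(self.ids, self.snps.loc[mask].reset_index(drop=True),
                             self.dosages[:, np.asarray(mask)])

    def subset_individuals(self, keep_ids: list[str]) -> "GenotypeTable":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = np.asarray([pos[i] for i in keep_ids])
        return GenotypeTable(list(keep_ids), self.snps.copy(), self.dosages[idx])


def _simulate_family(rng: np.random.Generator, fam_id: str, size: int,
                     ms_rate: float) -> list[dict]:
    """One three-generation pedigree with exactly ``size`` members.

    Grown nuclear-unit by nuclear-unit: start from a founder couple with one
    child, then repeatedly either add a child to an existing couple or marry
    an existing childless-by-marriage member to a new founder spouse,
    creating a new couple.  Households are nuclear: children carry the id of
    their parental couple.
    """
    if size < 3:
        raise ValueError("family size must be >= 3 for a founder couple with a child")
    members: list[dict] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{fam_id}_{counter}"

    def add(father, mother, sex, generation) -> dict:
        rec = {
            "individual_id": new_id(),
            "father_id": father, "mother_id": mother,
            "sex": sex,
            "family_id": fam_id,
            "household_id": f"{fam_id}_h_{father}_{mother}" if father else None,
            "status": None,
            "synthetic_founder": False,
            "_generation": generation,
        }
        members.append(rec)
        return rec

    pa = add(None, None, "male", 0)
    ma = add(None, None, "female", 0)
    couples = [(pa, ma)]
    add(pa["individual_id"], ma["individual_id"],
        "male" if rng.random() < 0.5 else "female", 1)

    while len(members) < size:
        # candidates to marry: gen-1/2 children without a spouse yet
        partnered = {c[0]["individual_id"] for c in couples} | {c[1]["individual_id"] for c in couples}
        singles = [m for m in members
                   if m["father_id"] is not None
                   and m["individual_id"] not in partnered
                   and m["_generation"] < 2]
        can_marry = len(members) + 1 < size or not couples  # spouse costs one slot
        if singles and can_marry and rng.random() < 0.4:
            child = singles[int(rng.integers(len(singles)))]
            spouse = add(None, None,
                         "female" if child["sex"] == "male" else "male",
                         child["_generation"])
            couple = (child, spouse) if child["sex"] == "male" else (spouse, child)
            couples.append(couple)
        else:
            f, m = couples[int(rng.integers(len(couples)))]
            gen = max(f["_generation"], m["_generation"]) + 1
            add(f["individual_id"], m["individual_id"],
                "male" if rng.random() < 0.5 else "female", min(gen, 2))
    for m in members:
        m["status"] = "case" if rng.random() < ms_rate else "control"
        if m["household_id"] is None:
            m["household_id"] = f"{fam_id}_h_founder_{m['individual_id']}"
        del m["_generation"]
    return members


def simulate_pedigree(config: SimulationConfig) -> PedigreeTable:
    """Generate ``n_families`` three-generation pedigrees (sizes uniform in
    the configured range), with households equal to nuclear families and
    case status assigned independently per individual."""
    lo, hi = config.family_sizes
    if lo > hi or lo < 3:
        raise ValueError(f"infeasible family size range ({lo}, {hi})")
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for k in range(config.n_families):
        size = int(rng.integers(lo, hi + 1))
        rows.extend(_simulate_family(rng, f"F{k + 1}", size,
                                     config.ms_prevalence_in_families))
    return PedigreeTable(pd.DataFrame(rows))


def add_singletons(ped: PedigreeTable, n: int, seed: int = 0,
                   status: str = "control") -> PedigreeTable:
    """Append ``n`` unrelated singletons, each its own family and household.

    Mirrors a study arm of extra unrelated controls: their off-diagonal
    entries in both A and H are zero by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n):
        iid = f"S{k + 1}"
        rows.append({
            "individual_id": iid, "father_id": None, "mother_id": None,
            "sex": "male" if rng.random() < 0.5 else "female",
            "family_id": f"SF{k + 1}", "household_id": f"SH{k + 1}",
            "status": status, "synthetic_founder": False,
        })
    tab = pd.concat([ped.table, pd.DataFrame(rows)], ignore_index=True)
    return PedigreeTable(tab, n_synthetic_founders=ped.n_synthetic_founders)


def gene_drop(ped: PedigreeTable, mafs, seed: int = 0,
              chromosome: str = "1", start_pos: int = 1_000_000) -> GenotypeTable:
    """Drop biallelic SNPs through the pedigree by Mendelian transmission.

    Founder alleles are Bernoulli(MAF) draws for the effect (minor) allele;
    each child inherits one uniformly chosen allele from each parent.
    SNPs are independent given the pedigree (no linkage).
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAF must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    tab = ped.table
    ids = ped.ids
    pos = {iid: k for k, iid in enumerate(ids)}
    from .pedigree import _topological_order
    order = _topological_order(tab)
    father = dict(zip(tab["individual_id"], tab["father_id"]))
    mother = dict(zip(tab["individual_id"], tab["mother_id"]))
    n, m = len(ids), len(mafs)
    # two allele slots per individual, all SNPs at once
    alleles = np.zeros((n, 2, m), dtype=np.int8)
    for iid in order:
        i = pos[iid]
        f, mo = father[iid], mother[iid]
        if f is None:
            alleles[i] = rng.random((2, m)) < mafs
        else:
            pick_f = rng.integers(2, size=m)
            pick_m = rng.integers(2, size=m)
            alleles[i, 0] = alleles[pos[f], pick_f, np.arange(m)]
            alleles[i, 1] = alleles[pos[mo], pick_m, np.arange(m)]
    dosages = alleles.sum(axis=1).astype(float)
    snps = pd.DataFrame({
        "snp_id": [f"snp{k + 1}" for k in range(m)],
        "chromosome": chromosome,
        "position": start_pos + 10_000 * np.arange(m),
        "effect_allele": "A",
        "reference_allele": "G",
    })
    return GenotypeTable(ids=ids, snps=snps, dosages=dosages)


def _block_sqrt(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition (eigenvalues clipped at 0)."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def simulate_phenotype(ped: PedigreeTable, structure: CovarianceStructure,
                       config: SimulationConfig,
                       genotypes: GenotypeTable | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """One trait vector under the additive-genetic + household + residual model.

    ``y = b_ms*MS + b_sex*SEX + sum(beta_s * dosage_s) + g + c + e`` with
    ``g ~ N(0, h2*A)``, ``c ~ N(0, c2*H)`` and residual variance
    ``1 - h2 - c2 - planted SNP variance`` so the total genetic+environment
    variance is 1 before fixed effects.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = structure.n
    tab = ped.table.set_index("individual_id").loc[structure.ids]
    sex = (tab["sex"] == "female").to_numpy(float)
    ms = (tab["status"] == "case").to_numpy(float)

    snp_var = 0.0
    snp_pred = np.zeros(n)
    if config.snp_effects:
        if genotypes is None:
            raise ValueError("snp_effects given but no genotypes")
        gpos = {iid: k for k, iid in enumerate(genotypes.ids)}
        gidx = np.asarray([gpos[i] for i in structure.ids])
        mafs = genotypes.maf()
        for snp_idx, beta in config.snp_effects:
            p = mafs[snp_idx]
            snp_var += 2.0 * p * (1.0 - p) * beta ** 2
            snp_pred += beta * genotypes.dosages[gidx, snp_idx]
    s2_e = 1.0 - config.h2_true - config.c2_true - snp_var
    if s2_e < -1e-12:
        raise ValueError("planted SNP variance exceeds the unit variance budget")
    s2_e = max(s2_e, 0.0)

    y = config.beta_ms * ms + config.beta_sex * sex + snp_pred
    if config.h2_true > 0:
        z = rng.standard_normal(n)
        g = np.zeros(n)
        for idx in structure.family_blocks():
            g[idx] = _block_sqrt(structure.A[np.ix_(idx, idx)]) @ z[idx]
        y = y + np.sqrt(config.h2_true) * g
    if config.c2_true > 0:
        z = rng.standard_normal(n)
        c = np.zeros(n)
        for idx in structure.family_blocks():
            c[idx] = _block_sqrt(structure.H[np.ix_(idx, idx)]) @ z[idx]
        y = y + np.sqrt(config.c2_true) * c
    y = y + np.sqrt(s2_e) * rng.standard_normal(n)
    return y


def planted_snp_study(total_explained: float = 0.40, n_planted: int = 3,
                      n_null_snps: int = 0, n_families: int = 20,
                      family_sizes: tuple[int, int] = (4, 6),
                      n_singletons: int = 60, h2: float = 0.2, c2: float = 0.05,
                      maf_range: tuple[float, float] = (0.2, 0.5),
                      seed: int = 0):
    """Controls-only study with a known SNP architecture.

    Emulates the pQTL sample design: ~20 small families of related controls
    plus unrelated singletons (~155 individuals total), with ``n_planted``
    SNPs whose additive effects are scaled from their realized allele
    frequencies so they jointly explain ``total_explained`` of the unit
    genetic+environmental+SNP variance.  Optional null SNPs pad the panel.

    Returns ``(ped, structure, genotypes, y, covariates, planted_ids)`` with
    ``y`` standardized and ``covariates`` holding the 0/1 sex column.
    """
    cfg = SimulationConfig(n_families=n_families, family_sizes=family_sizes,
                           h2_true=h2, c2_true=c2, beta_ms=0.0,
                           maf_range=maf_range, seed=seed)
    ped = simulate_pedigree(cfg)
    if n_singletons:
        ped = add_singletons(ped, n_singletons, seed=seed + 1)
    from .pedigree import covariance_structure
    structure = covariance_structure(ped)
    rng = np.random.default_rng(seed + 2)
    m = n_planted + n_null_snps
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m)
    gt = gene_drop(ped, mafs, seed=seed + 3)
    freqs = gt.maf()
    per_snp = total_explained / n_planted
    cfg.snp_effects = [
        (j, float(np.sqrt(per_snp / (2.0 * p * (1.0 - p)))))
        for j, p in enumerate(freqs[:n_planted])
    ]
    y = simulate_phenotype(ped, structure, cfg, gt, rng=np.random.default_rng(seed + 4))
    y = (y - y.mean()) / y.std(ddof=1)
    tab = ped.table.set_index("individual_id").loc[structure.ids]
    covariates = pd.DataFrame({"sex": (tab["sex"] == "female").to_numpy(float)})
    planted = [gt.snps.loc[j, "snp_id"] for j in range(n_planted)]
    return ped, structure, gt, y, covariates, planted


def simulate_dataset(config: SimulationConfig, n_singletons: int = 0,
                     n_traits: int = 1, n_planted: int = 0,
                     planted_variance: float = 0.0):
    """Convenience bundle: pedigree (+singletons), structure, genotypes, traits.

    Returns ``(ped, structure, genotypes, traits)`` where ``traits`` is a
    DataFrame of ``n_traits`` independent replicate traits sharing the same
    generative parameters.  Genotypes are generated when ``config.n_snps > 0``.
    ``n_planted`` > 0 assigns additive effects to the first SNPs, scaled from
    their realized allele frequencies to jointly explain ``planted_variance``.
    """
    ped = simulate_pedigree(config)
    if n_singletons:
        ped = add_singletons(ped, n_singletons, seed=config.seed + 1)
    structure = covariance_structure(ped)
    genotypes = None
    if config.n_snps > 0:
        rng = np.random.default_rng(config.seed + 2)
        lo, hi = config.maf_range
        mafs = rng.uniform(lo, hi, size=config.n_snps)
        genotypes = gene_drop(ped, mafs, seed=config.seed + 3)
        if n_planted > 0:
            if n_planted > config.n_snps:
                raise ValueError("cannot plant more SNPs than the panel holds")
            per_snp = planted_variance / n_planted
            freqs = genotypes.maf()
            config.snp_effects = [
                (j, float(np.sqrt(per_snp / (2.0 * p * (1.0 - p)))))
                for j, p in enumerate(freqs[:n_planted])
            ]
    rng = np.random.default_rng(config.seed + 4)
    traits = pd.DataFrame(
        {f"trait{k + 1}": simulate_phenotype(ped, structure, config, genotypes, rng=rng)
         for k in range(n_traits)},
        index=structure.ids,
    )
    return ped, structure, genotypes, traits
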