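"""File formats, run configuration and the end-to-end pipeline entry points.

Text formats used throughout:

* pedigree — whitespace-delimited ``.fam``-style rows
  (FID IID PAT MAT SEX STATUS [HOUSEHOLD]), missing parent "0";
* phenotypes — TSV with ``individual_id``, ``sex``, ``status`` and one
  column per trait;
* genotypes — a dosage TSV dialect: per-SNP metadata columns
  (snp_id, chromosome, position, effect_allele, reference_allele) followed
  by one column per individual holding dosages in {0, 1, 2} ("NA" missing);
* matrices — TSV with individual ids as header row and first column.

Every pipeline run writes a manifest (config, seed, package version, config
hash) next to its outputs so identical manifests imply byte-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .heritability import heritability_analysis
from .pedigree import PedigreeTable, covariance_structure
from .pqtl import explained_variance, qc_pipeline
from .simulate import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "write_matrix",
    "read_matrix",
    "run_heritability",
    "run_pqtl",
]

_SNP_META = ["snp_id", "chromosome", "position", "effect_allele", "reference_allele"]


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run; defaults are the study ones."""

    pedigree: str = ""
    phenotypes: str = ""
    genotypes: str = ""
    traits: list[str] = field(default_factory=list)
    out_dir: str = "results"
    fdr: float = 0.05
    level: float = 0.95
    maf: float = 0.05
    hwe: float = 1e-4
    r2: float = 0.2
    ld_window: int = 50
    ld_step: int = 5
    topk: int = 50
    alpha: float = 1e-4
    boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1 and 0 < self.level < 1):
            raise ValueError("fdr and level must lie in (0, 1)")
        if not (0 <= self.maf <= 0.5 and 0 < self.hwe < 1 and 0 < self.r2 <= 1):
            raise ValueError("QC thresholds out of range")
        if self.topk < 1 or self.alpha <= 0 or self.boot < 0:
            raise ValueError("selection parameters out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_manifest(config: RunConfig, out_dir: Path, stage: str) -> None:
    manifest = {"stage": stage, "config": asdict(config), "seed": config.seed,
                "config_hash": config.config_hash(), "version": __version__}
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def write_pedigree(ped: PedigreeTable, path) -> None:
    tab = ped.table
    sex = tab["sex"].map({"male": "1", "female": "2"})
    status = tab["status"].map({"control": "1", "case": "2"}).fillna("0")
    out = pd.DataFrame({
        "fid": tab["family_id"], "iid": tab["individual_id"],
        "pat": tab["father_id"].fillna("0"), "mat": tab["mother_id"].fillna("0"),
        "sex": sex, "status": status,
        "household": tab["household_id"].fillna("0"),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_phenotypes(traits: pd.DataFrame, covariates: pd.DataFrame, path) -> None:
    """TSV: individual_id, sex, status, one column per trait."""
    out = pd.DataFrame({"individual_id": traits.index})
    out["sex"] = covariates["sex"].to_numpy()
    out["status"] = covariates["status"].to_numpy()
    for c in traits.columns:
        out[c] = traits[c].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (traits indexed by individual_id, covariates with sex/status 0-1)."""
    tab = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    tab = tab.set_index("individual_id")
    cov = pd.DataFrame(index=tab.index)
    sex = tab["sex"].astype(str).str.strip().str.lower()
    cov["sex"] = sex.isin(["2", "2.0", "female", "f"]).astype(float)
    st = tab["status"].astype(str).str.strip().str.lower()
    cov["status"] = st.isin(["2", "2.0", "case"]).astype(float)
    traits = tab.drop(columns=["sex", "status"])
    return traits, cov.reset_index(drop=True)


def write_dosage_tsv(gt: GenotypeTable, path) -> None:
    meta = gt.snps[_SNP_META].copy()
    dos = pd.DataFrame(gt.dosages.T, columns=gt.ids)
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_dosage_tsv(path) -> GenotypeTable:
    tab = pd.read_csv(path, sep="\t", na_values="NA")
    snps = tab[_SNP_META].copy()
    ids = [c for c in tab.columns if c not in _SNP_META]
    dosages = tab[ids].to_numpy(dtype=float).T
    return GenotypeTable(ids=ids, snps=snps, dosages=dosages)


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def run_heritability(config: RunConfig, ped: PedigreeTable,
                     traits: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Heritability stage: validates ids, fits every trait, writes outputs.

    ``traits`` rows must be indexed by individual_id; every phenotyped
    individual must appear in the pedigree.
    """
    missing = [i for i in traits.index if i not in set(ped.ids)]
    if missing:
        raise ValueError(f"individuals in phenotypes but not pedigree: {missing}")
    if traits.shape[1] == 0:
        logger.warning("empty trait list; nothing to do")
        return pd.DataFrame()
    structure = covariance_structure(ped).subset(list(traits.index))
    table = heritability_analysis(traits, covariates, structure,
                                  level=config.level, fdr=config.fdr)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_out = table.copy()
    for c in table_out.columns:
        if table_out[c].dtype == float:
            table_out[c] = table_out[c].round(6)
    table_out.to_csv(out_dir / "heritability.tsv", sep="\t", index=False)
    _write_manifest(config, out_dir, "heritability")
    return table


def run_pqtl(config: RunConfig, ped: PedigreeTable, traits: pd.DataFrame,
             covariates: pd.DataFrame, gt: GenotypeTable,
             heritable_traits: list[str]) -> dict:
    """pQTL stage on controls only: QC, scan, selection, explained variance.

    Cases are excluded up front (the trait-disease direction cannot be
    resolved in affected individuals); the exclusion count is logged.
    """
    for t in heritable_traits:
        if t not in traits.columns:
            raise ValueError(f"trait {t!r} not present in phenotype table")
    is_control = covariates["status"].to_numpy() == 0
    n_cases = int((~is_control).sum())
    if n_cases:
        logger.info("excluding %d cases from the pQTL stage", n_cases)
    keep_ids = list(np.asarray(traits.index)[is_control])
    structure = covariance_structure(ped).subset(keep_ids)
    gt_c = gt.subset_individuals(keep_ids)
    cov_c = covariates.loc[is_control, ["sex"]].reset_index(drop=True)
    gt_qc, qc_report = qc_pipeline(gt_c, maf=config.maf, hwe=config.hwe,
                                   r2_max=config.r2, window=config.ld_window,
                                   step=config.ld_step)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
    results = {}
    from .heritability import standardize
    for t in heritable_traits:
        if gt_qc.n_snps == 0:
            logger.warning("no SNPs survived QC; empty scan for %s", t)
            results[t] = {"scan": pd.DataFrame(), "selected": [], "r2_snps": 0.0,
                          "ci": (0.0, 0.0), "effects": pd.DataFrame()}
            continue
        y = standardize(traits.loc[keep_ids, t].to_numpy(dtype=float))
        res = explained_variance(
            y, gt_qc, structure, cov_c, topk=config.topk, alpha=config.alpha,
            B=config.boot, level=config.level, seed=config.seed)
        results[t] = res
        eff = res["effects"].copy()
        if len(eff):
            eff["trait"] = t
            eff.to_csv(out_dir / f"pqtl_{t}_effects.tsv", sep="\t", index=False,
                       float_format="%.6g")
        summary = pd.DataFrame([{
            "trait": t, "r2_snps": res["r2_snps"], "ci_low": res["ci"][0],
            "ci_high": res["ci"][1], "B": res["B"], "n_selected": len(res["selected"]),
            "candidate_pool_size": res["candidate_pool_size"],
        }])
        summary.to_csv(out_dir / f"pqtl_{t}_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
    _write_manifest(config, out_dir, "pqtl")
    results["qc_report"] = qc_report
    return results
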