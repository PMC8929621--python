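"""Readers and writers for pedigree, phenotype, genotype and ring-series
files, plus the run configuration.

Column contracts
----------------
* Pedigree CSV: ``id, sire, dam[, group]``; unknown parents empty or
  ``UNKNOWN``; header required; UTF-8.
* Phenotype CSV (wide): ``tree, site, replication, group`` plus one column
  per trait; missing values empty or ``NA``.
* Ring-series CSV (long): ``tree, year, bai`` (or ``width``).
* Genotypes: VCF with biallelic records and GT fields (dosage = ALT-allele
  count), or a dosage TSV with individuals as rows, loci as columns and
  ``NA`` for missing.  Read-depth filtering happens upstream of these
  inputs and is not re-applied here.

All writers emit exactly the dialect the readers consume, so a write/read
round trip reproduces the in-memory structures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, StructuralError
from .genomic import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree
from .traits import RingSeries

# -- pedigree ---------------------------------------------------------------


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"id", "sire", "dam"}
    if not need <= set(df.columns):
        raise DataError(f"{path}: pedigree CSV needs columns {sorted(need)}")
    return Pedigree.from_frame(df)


def write_pedigree_csv(ped: Pedigree, path):
    ped.to_frame().to_csv(path, index=False)


# -- phenotypes -------------------------------------------------------------


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["", "NA"])
    need = {"tree", "site", "replication"}
    if not need <= set(df.columns):
        raise DataError(f"{path}: phenotype CSV needs columns {sorted(need)}")
    df["tree"] = df["tree"].astype(str)
    return df


def write_phenotypes_csv(table: pd.DataFrame, path):
    table.to_csv(path, index=False, na_rep="NA", float_format="%.10g")


# -- ring series ------------------------------------------------------------


def read_rings_csv(path) -> dict[str, RingSeries]:
    df = pd.read_csv(path)
    need = {"tree", "year", "bai"}
    if not need <= set(df.columns):
        raise DataError(f"{path}: ring CSV needs columns {sorted(need)}")
    out = {}
    for tree, grp in df.groupby("tree", sort=True):
        grp = grp.sort_values("year")
        out[str(tree)] = RingSeries(
            tree=str(tree),
            years=grp["year"].to_numpy(dtype=int),
            bai=grp["bai"].to_numpy(dtype=float),
        )
    return out


def write_rings_csv(rings: dict[str, RingSeries], path):
    rows = []
    for tree in sorted(rings):
        s = rings[tree]
        for y, b in zip(s.years, s.bai):
            rows.append({"tree": tree, "year": int(y), "bai": float(b)})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


# -- genotypes --------------------------------------------------------------


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        ids=[str(i) for i in df.index],
        loci=[str(c) for c in df.columns],
        M=df.to_numpy(dtype=float),
    )


def write_dosage_tsv(gm: GenotypeMatrix, path):
    gm.to_frame().to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_vcf(path) -> GenotypeMatrix:
    """Biallelic VCF records to ALT-allele dosages (0/1 -> 1, 1/1 -> 2, ./. -> NA)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = [str(s) for s in vcf.samples]
    loci, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic records only
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        col = np.empty(len(ids))
        for k, gt in enumerate(var.genotypes):
            a = [x for x in gt[:-1] if x is not None]
            if len(a) < 2 or min(a) < 0:
                col[k] = np.nan
            else:
                col[k] = float(sum(1 for x in a if x == 1))
        cols.append(col)
    vcf.close()
    if not loci:
        raise DataError(f"{path}: no biallelic records with GT found")
    return GenotypeMatrix(ids=ids, loci=loci, M=np.column_stack(cols))


def write_vcf(gm: GenotypeMatrix, path):
    """Write integer dosages as a minimal unphased single-chromosome VCF."""
    M = gm.M
    ok = np.isnan(M) | np.isin(M, (0.0, 1.0, 2.0))
    if not ok.all():
        raise DataError("VCF output requires integer dosages (filter/impute not applied)")
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.ids)
            + "\n"
        )
        for j, locus in enumerate(gm.loci):
            calls = [
                "./." if np.isnan(M[i, j]) else gt_of[M[i, j]]
                for i in range(len(gm.ids))
            ]
            fh.write(
                f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# -- run configuration ------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run (YAML round-trips)."""

    pedigree: str = ""
    phenotypes: str = ""
    genotypes: str = ""  # .vcf or .tsv
    rings: str = ""
    outdir: str = "results"
    seed: int = 0
    max_missing: float = 0.30
    min_mac: int = 1
    conflict_threshold: float = 0.15
    parent_window: tuple[float, float] = (0.35, 0.65)
    g_ridge: float = 1e-6
    drought_year: int = 2015
    pre_window: int = 4
    log_traits: list[str] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)
    sites: list[str] = field(default_factory=list)
    trait_pairs: list[tuple[str, str]] = field(default_factory=list)
    site_model_traits: list[str] = field(default_factory=list)
    min_obs: int = 30
    tol: float = 1e-8
    max_iter: int = 2000

    def validate(self):
        if not 0 <= self.max_missing <= 1:
            raise DataError("max_missing must be in [0, 1]")
        if self.min_mac < 1:
            raise DataError("min_mac must be >= 1")
        lo, hi = self.parent_window
        if not 0 <= lo < hi:
            raise DataError("parent_window must be an increasing interval")
        if self.min_obs < 1:
            raise DataError("min_obs must be >= 1")

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["parent_window"] = list(self.parent_window)
        d["trait_pairs"] = [list(p) for p in self.trait_pairs]
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = (
            Path(source).read_text()
            if isinstance(source, (str, Path)) and "\n" not in str(source)
            else str(source)
        )
        d = yaml.safe_load(text)
        d["parent_window"] = tuple(d.get("parent_window", (0.35, 0.65)))
        d["trait_pairs"] = [tuple(p) for p in d.get("trait_pairs", [])]
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class Dataset:
    pedigree: Pedigree
    genotypes: GenotypeMatrix | None
    phenotypes: pd.DataFrame | None
    rings: dict[str, RingSeries] | None
    reconciliation: dict


def load_dataset(config: RunConfig) -> Dataset:
    """Load and cross-validate all configured inputs.

    Ids present in one input but absent from the pedigree are never silently
    dropped: they are listed in the reconciliation report.
    """
    config.validate()
    ped = read_pedigree_csv(config.pedigree)
    gm = None
    if config.genotypes:
        if str(config.genotypes).endswith(".vcf"):
            gm = read_vcf(config.genotypes)
        else:
            gm = read_dosage_tsv(config.genotypes)
    pheno = read_phenotypes_csv(config.phenotypes) if config.phenotypes else None
    rings = read_rings_csv(config.rings) if config.rings else None

    ped_ids = set(ped.ids)
    rec = {"orphan_phenotypes": [], "orphan_genotypes": [], "orphan_rings": []}
    if pheno is not None:
        rec["orphan_phenotypes"] = sorted(
            {t for t in pheno["tree"].astype(str) if t not in ped_ids}
        )
    if gm is not None:
        rec["orphan_genotypes"] = sorted({i for i in gm.ids if i not in ped_ids})
    if rings is not None:
        rec["orphan_rings"] = sorted({t for t in rings if t not in ped_ids})
    return Dataset(
        pedigree=ped, genotypes=gm, phenotypes=pheno, rings=rings, reconciliation=rec
    )


def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))
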