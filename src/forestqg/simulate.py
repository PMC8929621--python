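"""Synthetic open-pollinated progeny-trial data with known truth.

The generators emulate a multi-site open-pollinated (OP) white-spruce progeny
trial: mothers (dams) with recorded identity, wind-borne fathers drawn from a
finite pollen pool and hidden from the field records, a small rate of
mislabelled mothers, genotyping-by-sequencing-style SNP dosages with
missingness, multi-trait multi-site phenotypes with a specified genetic
covariance, and annual basal-area-increment series with a single discrete
drought year.

Defaults reflect the emulated trial: 80 families of 8 progeny over 3 sites,
a pollen pool of 100 donors, biallelic SNPs with up to 30% missing calls,
ring series spanning 1995-2016 with the drought in 2015 and a drought
severity of 0.43 so that the population mean Resistance sits near 0.57.

Every generator draws from a single ``numpy.random.default_rng(seed)``; the
same seed replays byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, StructuralError
from .genomic import GenotypeMatrix
from .pedigree import (
    UNKNOWN,
    Pedigree,
    RelationshipMatrix,
    validate_and_order,
)
from .traits import RingSeries


@dataclass
class TraitConfig:
    """Generative settings for multi-trait multi-site phenotypes.

    Responses are trait-site combinations ordered traits-major:
    ``[(t, s) for t in traits for s in sites]``.  Phenotypic variance is 1
    per response, so the additive variance of a response equals its
    heritability.
    """

    traits: list[str]
    sites: list[str]
    heritability: dict  # (trait, site) -> h2 in [0, 1]
    genetic_correlation: np.ndarray | None = None  # across responses
    residual_correlation: np.ndarray | None = None  # across traits, within site
    site_means: dict = field(default_factory=dict)  # (trait, site) -> mean
    replication_sd: float = 0.25
    group_effect_sd: float = 0.0
    lognormal: dict = field(default_factory=dict)  # trait -> bool
    missing_rate: dict = field(default_factory=dict)  # trait -> proportion

    @property
    def responses(self) -> list[tuple[str, str]]:
        return [(t, s) for t in self.traits for s in self.sites]

    def validate(self):
        r = len(self.responses)
        for key in self.responses:
            h2 = self.heritability.get(key)
            if h2 is None or not 0 <= h2 <= 1:
                raise ParameterError(f"heritability for {key} must be in [0, 1]")
        for name, mat, dim in (
            ("genetic_correlation", self.genetic_correlation, r),
            ("residual_correlation", self.residual_correlation, len(self.traits)),
        ):
            if mat is None:
                continue
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (dim, dim):
                raise ParameterError(f"{name} must be {dim}x{dim}")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ParameterError(f"{name} must be symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
                raise ParameterError(f"{name} must have unit diagonal")
            if np.linalg.eigvalsh(mat)[0] < -1e-8:
                raise ParameterError(f"{name} must be positive semidefinite")

    def sigma_a(self) -> np.ndarray:
        """Genetic covariance across responses implied by h2 and correlations."""
        self.validate()
        sd = np.sqrt([self.heritability[key] for key in self.responses])
        R = (
            np.eye(len(sd))
            if self.genetic_correlation is None
            else np.asarray(self.genetic_correlation, dtype=float)
        )
        return R * np.outer(sd, sd)


@dataclass
class SimulationTruth:
    """Everything the generators know that an analyst would not."""

    true_pedigree: Pedigree
    recorded_pedigree: Pedigree
    seed: int
    contamination_events: list = field(default_factory=list)
    swap_events: list = field(default_factory=list)
    true_variance_components: dict = field(default_factory=dict)
    true_breeding_values: pd.DataFrame | None = None

    @property
    def progeny(self) -> list[str]:
        rec = self.recorded_pedigree
        return [
            i for i, s, d in zip(rec.ids, rec.sires, rec.dams)
            if not (s == UNKNOWN and d == UNKNOWN)
        ]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "true_pedigree": self.true_pedigree.to_frame().to_dict("list"),
            "recorded_pedigree": self.recorded_pedigree.to_frame().to_dict("list"),
            "contamination_events": self.contamination_events,
            "swap_events": self.swap_events,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        payload = json.loads(text)
        return cls(
            true_pedigree=Pedigree.from_frame(pd.DataFrame(payload["true_pedigree"])),
            recorded_pedigree=Pedigree.from_frame(
                pd.DataFrame(payload["recorded_pedigree"])
            ),
            seed=int(payload["seed"]),
            contamination_events=[tuple(e) for e in payload["contamination_events"]],
            swap_events=[tuple(e) for e in payload["swap_events"]],
        )


def simulate_pedigree(
    n_dams: int = 80,
    progeny_per_dam: int = 8,
    pollen_pool_size: int = 100,
    contamination_rate: float = 0.0,
    seed: int = 0,
) -> SimulationTruth:
    """Open-pollinated pedigree with hidden sires and optional dam mislabels.

    Every progeny has a true dam and a true sire drawn uniformly from the
    pollen pool (selfing excluded by construction: donors are distinct
    individuals from the dams).  The recorded pedigree hides all sires and,
    with probability ``contamination_rate``, replaces the recorded dam by a
    different dam; each such event is logged as
    ``(offspring, recorded_dam, true_dam)``.
    """
    if min(n_dams, progeny_per_dam, pollen_pool_size) < 1:
        raise ParameterError("counts must be >= 1")
    if not 0 <= contamination_rate <= 1:
        raise ParameterError("contamination_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    dams = [f"D{k:04d}" for k in range(1, n_dams + 1)]
    sires = [f"S{k:04d}" for k in range(1, pollen_pool_size + 1)]
    progeny, true_dam, true_sire, rec_dam = [], [], [], []
    events = []
    k = 0
    for dam in dams:
        for _ in range(progeny_per_dam):
            k += 1
            child = f"P{k:05d}"
            sire = sires[rng.integers(pollen_pool_size)]
            recorded = dam
            if n_dams > 1 and rng.random() < contamination_rate:
                other = dams[rng.integers(n_dams - 1)]
                if other == dam:
                    other = dams[-1]
                recorded = other
                events.append((child, recorded, dam))
            progeny.append(child)
            true_dam.append(dam)
            true_sire.append(sire)
            rec_dam.append(recorded)

    groups = {d: f"PROV{(i % 4) + 1}" for i, d in enumerate(dams)}
    for child, dam in zip(progeny, true_dam):
        groups[child] = groups[dam]

    true_ped = Pedigree(
        ids=dams + sires + progeny,
        sires=[UNKNOWN] * (n_dams + pollen_pool_size) + true_sire,
        dams=[UNKNOWN] * (n_dams + pollen_pool_size) + true_dam,
        groups=dict(groups),
    )
    recorded_ped = Pedigree(
        ids=dams + progeny,
        sires=[UNKNOWN] * n_dams + [UNKNOWN] * len(progeny),
        dams=[UNKNOWN] * n_dams + rec_dam,
        groups=dict(groups),
    )
    return SimulationTruth(
        true_pedigree=validate_and_order(true_ped),
        recorded_pedigree=validate_and_order(recorded_ped),
        seed=int(seed),
        contamination_events=events,
    )


def simulate_genotypes(
    truth: SimulationTruth,
    n_snps: int = 3000,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop biallelic SNP dosages through the true pedigree.

    Founder allele frequencies are uniform on [maf_low, maf_high]; founders
    are in Hardy-Weinberg equilibrium; each non-founder inherits one allele
    per parent per locus, with unknown parents replaced by fresh
    population-frequency draws.  Loci are unlinked.  Missing entries are
    masked completely at random at ``missing_rate``.
    """
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ParameterError("need 0 < maf_low <= maf_high <= 0.5")
    if not 0 <= missing_rate < 1:
        raise ParameterError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ped = truth.true_pedigree  # already topologically ordered
    from .pedigree import _parent_indices

    s_idx, d_idx = _parent_indices(ped)
    n = len(ped)
    p = rng.uniform(maf_low, maf_high, size=n_snps)

    alleles = np.zeros((n, 2, n_snps), dtype=np.int8)
    for i in range(n):
        for slot, parent in enumerate((s_idx[i], d_idx[i])):
            if parent < 0:
                alleles[i, slot] = rng.random(n_snps) < p
            else:
                pick = rng.integers(2, size=n_snps)
                alleles[i, slot] = alleles[parent, pick, np.arange(n_snps)]
    M = alleles.sum(axis=1).astype(float)
    if missing_rate > 0:
        M[rng.random(M.shape) < missing_rate] = np.nan
    loci = [f"SNP{j:06d}" for j in range(1, n_snps + 1)]
    return GenotypeMatrix(ids=list(ped.ids), loci=loci, M=M)


def assign_sites_and_reps(
    truth: SimulationTruth,
    sites: list[str] = ("CALL", "CARS", "REDE"),
    n_reps: int = 4,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Scatter each family's progeny across sites and replications.

    Progeny of every family are dealt round-robin over sites (so families are
    represented everywhere, as in a progeny trial) and uniformly over
    replications within site.
    """
    rng = np.random.default_rng(seed)
    sites = list(sites)
    site_of, rep_of = {}, {}
    rec = truth.recorded_pedigree
    by_dam: dict[str, list[str]] = {}
    for child, dam in zip(rec.ids, rec.dams):
        if dam != UNKNOWN:
            by_dam.setdefault(dam, []).append(child)
    for dam in sorted(by_dam):
        kids = by_dam[dam]
        offset = rng.integers(len(sites))
        for j, child in enumerate(kids):
            s = sites[(j + offset) % len(sites)]
            site_of[child] = s
            rep_of[child] = f"{s}-R{rng.integers(n_reps) + 1}"
    return site_of, rep_of


def simulate_phenotypes(
    truth: SimulationTruth,
    relationship: RelationshipMatrix,
    config: TraitConfig,
    site_assignment: dict,
    replication_layout: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes from breeding values with covariance Sigma_a (x) K.

    Breeding values over all individuals of ``relationship`` are multivariate
    normal with the Kronecker covariance; replication effects are iid normal;
    residuals are correlated across traits within an individual but have zero
    covariance across sites (each tree grows at exactly one site).  The
    phenotype of tree i for trait t is recorded only for the tree's own site.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    responses = config.responses
    Sigma_a = config.sigma_a()
    eig = np.linalg.eigvalsh(Sigma_a)
    if eig[0] < -1e-8:
        raise ParameterError("genetic covariance is not positive semidefinite")

    trees = [t for t in site_assignment if t in set(relationship.ids)]
    missing_ids = [t for t in site_assignment if t not in set(relationship.ids)]
    if missing_ids:
        raise StructuralError(
            f"phenotyped trees absent from relationship matrix: {missing_ids[:5]}"
        )

    ids = relationship.ids
    q, r = len(ids), len(responses)
    # a = L_K Z L_S', Z iid standard normal
    wK, VK = np.linalg.eigh(relationship.values)
    LK = VK * np.sqrt(np.clip(wK, 0, None))
    wS, VS = np.linalg.eigh(Sigma_a)
    LS = VS * np.sqrt(np.clip(wS, 0, None))
    bv = LK @ rng.standard_normal((q, r)) @ LS.T
    bv_df = pd.DataFrame(bv, index=ids, columns=[f"{t}@{s}" for t, s in responses])

    Re = (
        np.eye(len(config.traits))
        if config.residual_correlation is None
        else np.asarray(config.residual_correlation, dtype=float)
    )
    Le = np.linalg.cholesky(Re + 1e-12 * np.eye(len(Re)))

    rep_levels = sorted(set(replication_layout.values()))
    rep_eff = {lv: rng.normal(0, config.replication_sd) for lv in rep_levels}
    group_eff = {}
    rows = []
    idx_of = {i: k for k, i in enumerate(ids)}
    for tree in trees:
        site = site_assignment[tree]
        rep = replication_layout.get(tree, "R1")
        grp = truth.recorded_pedigree.groups.get(tree, "G1")
        if config.group_effect_sd > 0 and grp not in group_eff:
            group_eff[grp] = rng.normal(0, config.group_effect_sd)
        z = Le @ rng.standard_normal(len(config.traits))
        row = {"tree": tree, "site": site, "replication": rep, "group": grp}
        for ti, trait in enumerate(config.traits):
            h2 = config.heritability[(trait, site)]
            e = np.sqrt(max(1.0 - h2, 0.0)) * z[ti]
            val = (
                config.site_means.get((trait, site), 0.0)
                + group_eff.get(grp, 0.0)
                + rep_eff[rep]
                + bv[idx_of[tree], responses.index((trait, site))]
                + e
            )
            if config.lognormal.get(trait, False):
                val = float(np.exp(val))
            row[trait] = val
        rows.append(row)
    table = pd.DataFrame(rows)

    for trait, rate in config.missing_rate.items():
        if rate > 0:
            mask = rng.random(len(table)) < rate
            table.loc[mask, trait] = np.nan

    truth.true_variance_components = {
        "responses": [f"{t}@{s}" for t, s in responses],
        "Sigma_a": Sigma_a,
        "residual_correlation": Re,
        "replication_sd": config.replication_sd,
    }
    truth.true_breeding_values = bv_df
    return table


def simulate_ring_series(
    truth: SimulationTruth,
    years: range = range(1995, 2017),
    drought_year: int = 2015,
    drought_severity: float = 0.43,
    sensitivity_noise: float = 0.20,
    resistance_sd: float = 0.25,
    mean_bai: float = 500.0,
    seed: int = 0,
) -> dict[str, RingSeries]:
    """Per-tree BAI series with a multiplicative drought-year dip.

    Each tree has a lognormal level, iid lognormal year noise with log-scale
    SD ``sensitivity_noise``, and in the drought year a multiplier
    ``1 - severity * (1 - g_i)`` where ``g_i`` is the tree's genetic
    resistance deviate (mean 0, SD ``resistance_sd``).  With the default
    severity of 0.43 the population mean Resistance index is close to 0.57,
    the level observed in drought-stressed OP spruce trials.
    """
    years = list(years)
    if not years:
        raise ParameterError("empty year range")
    if drought_year not in years:
        raise ParameterError("drought_year must fall inside years")
    if not 0 <= drought_severity <= 1:
        raise ParameterError("drought_severity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {}
    d_pos = years.index(drought_year)
    for tree in truth.progeny:
        level = mean_bai * np.exp(rng.normal(0, 0.3))
        noise = np.exp(rng.normal(0, sensitivity_noise, size=len(years)))
        g = rng.normal(0, resistance_sd)
        bai = level * noise
        bai[d_pos] *= float(np.clip(1.0 - drought_severity * (1.0 - g), 0.0, 1.5))
        out[tree] = RingSeries(tree=tree, years=np.array(years), bai=bai)
    return out


def degrade_pedigree(
    truth: SimulationTruth, error_rate: float, seed: int = 0
) -> Pedigree:
    """Swap recorded dam labels among families for a fraction of progeny.

    Each selected progeny is relabelled to a uniformly chosen *other* dam;
    the swap list is stored in ``truth.swap_events`` as
    ``(offspring, new_recorded_dam, previous_recorded_dam)`` tuples.
    """
    if not 0 <= error_rate <= 1:
        raise ParameterError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rec = truth.recorded_pedigree
    dams = sorted({d for d in rec.dams if d != UNKNOWN})
    new_dams = list(rec.dams)
    events = []
    if len(dams) > 1 and error_rate > 0:
        for k, (child, dam) in enumerate(zip(rec.ids, rec.dams)):
            if dam == UNKNOWN:
                continue
            if rng.random() < error_rate:
                others = [d for d in dams if d != dam]
                new = others[rng.integers(len(others))]
                new_dams[k] = new
                events.append((child, new, dam))
    truth.swap_events = events
    return Pedigree(
        ids=list(rec.ids),
        sires=list(rec.sires),
        dams=new_dams,
        groups=dict(rec.groups),
    )
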