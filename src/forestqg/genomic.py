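"""SNP dosage handling, the VanRaden genomic relationship matrix, and
SNP-based pedigree verification and correction.

Genotypes are coded 0/1/2 as the count of alternative alleles.  The genomic
relationship matrix is

    G = W W' / (2 * sum_i p_i (1 - p_i)),   W = M - 2 p

with ``p`` the per-locus alternative-allele frequency.  With sample
frequencies the columns of W sum to zero, so the grand sum of G is zero — a
useful end-to-end identity checked by the tests.

Pedigree verification compares realized coefficients g_ij against the
pedigree expectation for each pair class (0.5 parent-offspring and full-sib,
0.25 half-sib): pairs deviating by more than a configurable threshold are
flagged, and conflicted offspring are reassigned to the unique recorded
parent whose g falls inside a parent window, or to a fresh phantom parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, StructuralError
from .pedigree import (
    CLASS_FULL_SIB,
    CLASS_HALF_SIB,
    CLASS_PARENT_OFFSPRING,
    UNKNOWN,
    Pedigree,
    RelationshipMatrix,
)

#: Reserved id prefix for phantom parents created during pedigree correction.
PHANTOM_PREFIX = "PHANTOM_"

#: Pedigree expectations for realized relationships, by pair class.
CLASS_EXPECTATION = {
    CLASS_PARENT_OFFSPRING: 0.5,
    CLASS_FULL_SIB: 0.5,
    CLASS_HALF_SIB: 0.25,
}


@dataclass
class GenotypeMatrix:
    """Individuals x loci dosage matrix.

    ``M`` holds dosages in {0, 1, 2} with ``nan`` for missing before
    imputation, and real values in [0, 2] afterwards.
    """

    ids: list[str]
    loci: list[str]
    M: np.ndarray

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.loci = [str(l) for l in self.loci]
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (len(self.ids), len(self.loci)):
            raise StructuralError(
                f"dosage shape {self.M.shape} != ({len(self.ids)}, {len(self.loci)})"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.M, initial=0) < 0 or np.nanmax(self.M, initial=0) > 2:
                raise DataError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.M)

    def allele_frequency(self) -> np.ndarray:
        """Per-locus alternative-allele frequency from observed dosages."""
        return np.nanmean(self.M, axis=0) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.ids, columns=self.loci)


@dataclass
class ConflictReport:
    """Flagged pedigree/genomic disagreements and the actions taken."""

    pairs: pd.DataFrame  # id_a, id_b, class, expected, observed, deviation, action
    threshold: float
    actions: dict = field(default_factory=dict)

    @property
    def n_conflicts(self) -> int:
        return len(self.pairs)

    def conflicted_offspring(self) -> list[str]:
        po = self.pairs[self.pairs["class"] == CLASS_PARENT_OFFSPRING]
        return sorted(set(po["offspring"]))

    def to_json_summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_conflicts": int(self.n_conflicts),
            "actions": {k: int(v) for k, v in self.actions.items()},
        }


def filter_genotypes(
    gm: GenotypeMatrix, max_missing: float = 0.30, min_mac: int = 1
) -> GenotypeMatrix:
    """Drop loci by missingness and minor allele count.

    A locus is retained when its missing fraction is <= ``max_missing``
    (boundary inclusive) and its minor allele count among observed calls is
    >= ``min_mac``; monomorphic loci always fail the MAC criterion.
    Individuals are never dropped.
    """
    if not 0 <= max_missing <= 1:
        raise ParameterError("max_missing must be in [0, 1]")
    if min_mac < 1:
        raise ParameterError("min_mac must be >= 1")
    miss_frac = gm.missing_mask.mean(axis=0)
    alt = np.nansum(gm.M, axis=0)  # per-locus alt allele count
    n_obs = (~gm.missing_mask).sum(axis=0)
    total = 2.0 * n_obs
    mac = np.minimum(alt, total - alt)
    keep = (miss_frac <= max_missing) & (mac >= min_mac) & (n_obs > 0)
    if not keep.any():
        raise DataError("no loci survive filtering")
    return GenotypeMatrix(
        ids=list(gm.ids),
        loci=[l for l, k in zip(gm.loci, keep) if k],
        M=gm.M[:, keep],
    )


def impute_mean(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by its locus mean of observed calls."""
    n_obs = (~gm.missing_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [l for l, n in zip(gm.loci, n_obs) if n == 0]
        raise DataError(f"loci with zero observed calls: {bad[:5]}")
    M = gm.M.copy()
    means = np.nanmean(M, axis=0)
    rows, cols = np.nonzero(np.isnan(M))
    M[rows, cols] = means[cols]
    return GenotypeMatrix(ids=list(gm.ids), loci=list(gm.loci), M=M)


def compute_G(
    gm: GenotypeMatrix,
    freq_source: str = "sample",
    frequencies: np.ndarray | None = None,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = WW' / (2 sum p(1-p))."""
    if np.isnan(gm.M).any():
        raise DataError("impute missing dosages before computing G")
    if freq_source == "sample":
        p = gm.M.mean(axis=0) / 2.0
    elif freq_source == "provided":
        if frequencies is None:
            raise ParameterError("freq_source='provided' requires frequencies")
        p = np.asarray(frequencies, dtype=float)
        if p.shape != (gm.n_loci,):
            raise ParameterError("frequencies length must match locus count")
    else:
        raise ParameterError(f"unknown freq_source: {freq_source!r}")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise DataError("all loci monomorphic: zero denominator in G")
    W = gm.M - 2.0 * p
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(ids=list(gm.ids), values=G, kind="G")


def stabilize_G(
    G: RelationshipMatrix,
    method: str = "ridge",
    param: float = 1e-6,
    A: RelationshipMatrix | None = None,
) -> RelationshipMatrix:
    """Make G safely invertible by ridge loading or blending with A.

    ``ridge`` adds ``param`` to the diagonal; ``blend_with_A`` returns
    ``param * G + (1 - param) * A`` (``param`` is the G weight), the common
    preprocessing applied before inverting a genomic matrix.
    """
    if method == "ridge":
        vals = G.values + param * np.eye(len(G.ids))
        kind = G.kind
    elif method == "blend_with_A":
        if A is None:
            raise ParameterError("blend_with_A requires A")
        if A.ids != G.ids:
            raise StructuralError("A and G must share the same id ordering")
        if not 0 <= param <= 1:
            raise ParameterError("blend weight must be in [0, 1]")
        vals = param * G.values + (1.0 - param) * A.values
        kind = "G" if param == 1.0 else "blended"
    else:
        raise ParameterError(f"unknown stabilization method: {method!r}")
    return RelationshipMatrix(ids=list(G.ids), values=vals, kind=kind)


def _recorded_parent_pairs(ped: Pedigree, in_G: set[str]):
    """Yield (offspring, parent, role) for genotyped recorded parent pairs."""
    for child, s, d in zip(ped.ids, ped.sires, ped.dams):
        if child not in in_G:
            continue
        if s != UNKNOWN and s in in_G:
            yield child, s, "sire"
        if d != UNKNOWN and d in in_G:
            yield child, d, "dam"


def detect_conflicts(
    ped: Pedigree,
    G: RelationshipMatrix,
    deviation_threshold: float = 0.15,
) -> ConflictReport:
    """Flag pedigree pairs whose realized g deviates from expectation.

    Checks every (offspring, recorded parent) pair against 0.5, and every
    recorded full- or half-sib pair against 0.5 / 0.25.
    """
    if not 0 < deviation_threshold:
        raise ParameterError("deviation_threshold must be positive")
    shared = [i for i in G.ids if i in set(ped.ids)]
    if not shared:
        raise StructuralError("no shared ids between pedigree and G")
    in_G = set(G.ids)

    rows = []
    for child, parent, role in _recorded_parent_pairs(ped, in_G):
        g = G.loc(child, parent)
        dev = g - 0.5
        if abs(dev) > deviation_threshold:
            rows.append(
                {
                    "offspring": child,
                    "partner": parent,
                    "class": CLASS_PARENT_OFFSPRING,
                    "role": role,
                    "expected": 0.5,
                    "observed": g,
                    "deviation": dev,
                    "action": "pending",
                }
            )

    # Sib pairs among genotyped individuals, classified from recorded parents.
    from .pedigree import classify_pairs

    labels = classify_pairs(ped, shared)
    idx = G.indices(shared)
    sub = G.values[np.ix_(idx, idx)]
    for cls in (CLASS_FULL_SIB, CLASS_HALF_SIB):
        exp = CLASS_EXPECTATION[cls]
        ii, jj = np.nonzero(np.triu(labels == cls, k=1))
        g = sub[ii, jj]
        dev = g - exp
        bad = np.abs(dev) > deviation_threshold
        for a, b, gv, dv in zip(ii[bad], jj[bad], g[bad], dev[bad]):
            rows.append(
                {
                    "offspring": shared[a],
                    "partner": shared[b],
                    "class": cls,
                    "role": "sib",
                    "expected": exp,
                    "observed": float(gv),
                    "deviation": float(dv),
                    "action": "pending",
                }
            )

    pairs = pd.DataFrame(
        rows,
        columns=[
            "offspring",
            "partner",
            "class",
            "role",
            "expected",
            "observed",
            "deviation",
            "action",
        ],
    )
    return ConflictReport(pairs=pairs, threshold=deviation_threshold)


def correct_pedigree(
    ped: Pedigree,
    G: RelationshipMatrix,
    report: ConflictReport,
    parent_window: tuple[float, float] = (0.35, 0.65),
) -> tuple[Pedigree, ConflictReport]:
    """Reassign conflicted offspring to candidate parents supported by G.

    For each offspring whose recorded parent fails the realized-relationship
    check, candidate parents are searched among the recorded parents of the
    population: a unique candidate with g inside ``parent_window`` is
    assigned; ties or an empty candidate set produce a phantom parent.
    Offspring conflicting with two or more distinct recorded parents of the
    same role across checks are listed for removal.
    """
    lo, hi = parent_window
    if not 0 <= lo < hi:
        raise ParameterError("parent_window must be an increasing interval")

    in_G = set(G.ids)
    recorded_parents = sorted(
        {p for p in ped.sires + ped.dams if p != UNKNOWN and p in in_G}
    )
    new_sires = dict(zip(ped.ids, ped.sires))
    new_dams = dict(zip(ped.ids, ped.dams))

    pairs = report.pairs.copy()
    actions = {"reassigned": 0, "phantom": 0, "removed": 0, "unchanged": 0}
    phantom_counter = 0
    removal: list[str] = []

    po = pairs[pairs["class"] == CLASS_PARENT_OFFSPRING]
    for child, grp in po.groupby("offspring"):
        roles = set(grp["role"])
        if len(grp) > 1 and len(roles) < len(grp):
            # multi-way conflict on the same parental role: irreconcilable
            removal.append(child)
            pairs.loc[grp.index, "action"] = "remove"
            actions["removed"] += 1
            continue
        for ridx, row in grp.iterrows():
            role = row["role"]
            candidates = [
                p
                for p in recorded_parents
                if p != child and lo <= G.loc(child, p) <= hi
            ]
            if len(candidates) == 1:
                target = candidates[0]
                if role == "dam":
                    new_dams[child] = target
                else:
                    new_sires[child] = target
                pairs.loc[ridx, "action"] = f"reassigned:{target}"
                actions["reassigned"] += 1
            else:
                phantom_counter += 1
                phantom = f"{PHANTOM_PREFIX}{phantom_counter:04d}"
                if role == "dam":
                    new_dams[child] = phantom
                else:
                    new_sires[child] = phantom
                pairs.loc[ridx, "action"] = f"phantom:{phantom}"
                actions["phantom"] += 1

    sib_mask = pairs["class"] != CLASS_PARENT_OFFSPRING
    pairs.loc[sib_mask & (pairs["action"] == "pending"), "action"] = "reported"
    actions["unchanged"] = int((pairs["action"] == "reported").sum())

    ids = list(ped.ids)
    phantoms = sorted(
        {
            p
            for p in list(new_sires.values()) + list(new_dams.values())
            if p.startswith(PHANTOM_PREFIX)
        }
    )
    groups = dict(ped.groups)
    # Phantom parents inherit their offspring's genetic group (flagged choice).
    for child in ids:
        for p in (new_sires[child], new_dams[child]):
            if p.startswith(PHANTOM_PREFIX) and child in groups:
                groups.setdefault(p, groups[child])
    corrected = Pedigree(
        ids=phantoms + ids,
        sires=[UNKNOWN] * len(phantoms) + [new_sires[i] for i in ids],
        dams=[UNKNOWN] * len(phantoms) + [new_dams[i] for i in ids],
        groups=groups,
    )
    out_report = ConflictReport(
        pairs=pairs, threshold=report.threshold, actions=actions
    )
    out_report.removal_list = removal  # type: ignore[attr-defined]
    return corrected, out_report
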