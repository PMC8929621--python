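"""Independent oracles used by the tests.

These deliberately avoid the package's own computational paths: coancestry
by direct recursion, identity-by-descent by Monte-Carlo gene dropping on
labelled founder alleles, and variance components by the closed-form
one-way ANOVA method of moments.
"""

from __future__ import annotations

import numpy as np

from forestqg.pedigree import UNKNOWN, Pedigree


def kinship_matrix_oracle(ped: Pedigree) -> np.ndarray:
    """Additive relationships from the recursive coancestry definition.

    f(i, i) = (1 + f(s_i, d_i)) / 2 and, for i later than j,
    f(i, j) = (f(s_i, j) + f(d_i, j)) / 2, with unknown parents contributing
    zero coancestry.  Returns 2f (the numerator relationship).
    """
    order = {iid: k for k, iid in enumerate(ped.ids)}
    parents = {i: (s, d) for i, s, d in zip(ped.ids, ped.sires, ped.dams)}
    memo: dict[tuple[str, str], float] = {}

    def f(a: str, b: str) -> float:
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        key = (a, b) if order[a] <= order[b] else (b, a)
        if key in memo:
            return memo[key]
        i, j = key[1], key[0]  # i is the later individual
        si, di = parents[i]
        if i == j:
            val = 0.5 * (1.0 + f(si, di))
        else:
            val = 0.5 * (f(si, j) + f(di, j))
        memo[key] = val
        return val

    n = len(ped.ids)
    A = np.empty((n, n))
    for a, ia in enumerate(ped.ids):
        for b in range(a, n):
            A[a, b] = A[b, a] = 2.0 * f(ia, ped.ids[b])
    # self-relationship: a_ii = 1 + F = 2 f_ii? no: 2 f_ii = 1 + F already
    return A


def gene_drop_relationships(ped: Pedigree, n_drops: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo IBD estimates of the numerator relationships.

    Founders receive unique allele labels; alleles are dropped through the
    pedigree ``n_drops`` times.  Per drop and ordered pair (i, j), the
    kinship draw is the fraction of the four cross-individual allele
    comparisons that are IBD (for i = j, whether the two alleles are IBD,
    mapped to (1 + F)/2).  Returns (mean 2f, standard error of 2f).
    """
    order = {iid: k for k, iid in enumerate(ped.ids)}
    n = len(ped.ids)
    s_idx = np.array(
        [order[s] if s != UNKNOWN else -1 for s in ped.sires], dtype=int
    )
    d_idx = np.array(
        [order[d] if d != UNKNOWN else -1 for d in ped.dams], dtype=int
    )
    a1 = np.zeros((n, n_drops), dtype=np.int64)
    a2 = np.zeros((n, n_drops), dtype=np.int64)
    label = 1
    for i in range(n):
        for slot, parent, arr in ((0, s_idx[i], a1), (1, d_idx[i], a2)):
            if parent < 0:
                arr[i] = np.arange(label, label + n_drops)
                label += n_drops
            else:
                pick = rng.integers(2, size=n_drops).astype(bool)
                arr[i] = np.where(pick, a1[parent], a2[parent])
    mean = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                draws = 1.0 + (a1[i] == a2[i]).astype(float)  # 1 + F per drop
            else:
                draws = 0.5 * (
                    (a1[i] == a1[j]).astype(float)
                    + (a1[i] == a2[j]).astype(float)
                    + (a2[i] == a1[j]).astype(float)
                    + (a2[i] == a2[j]).astype(float)
                )
            mean[i, j] = mean[j, i] = draws.mean()
            se[i, j] = se[j, i] = draws.std(ddof=1) / np.sqrt(n_drops)
    return mean, se


def random_pedigree(rng, n: int, founder_fraction: float = 0.3) -> Pedigree:
    """Random acyclic pedigree: parents drawn from earlier individuals."""
    ids = [f"I{k:03d}" for k in range(n)]
    sires, dams = [], []
    n_founders = max(2, int(founder_fraction * n))
    for k in range(n):
        if k < n_founders:
            sires.append(UNKNOWN)
            dams.append(UNKNOWN)
            continue
        s = ids[rng.integers(k)] if rng.random() < 0.8 else UNKNOWN
        d = ids[rng.integers(k)] if rng.random() < 0.8 else UNKNOWN
        if s != UNKNOWN and s == d:
            d = UNKNOWN
        sires.append(s)
        dams.append(d)
    return Pedigree(ids=ids, sires=sires, dams=dams)


def anova_halfsib(y: np.ndarray, family: np.ndarray) -> tuple[float, float]:
    """Balanced one-way ANOVA method of moments on half-sib families.

    Returns the animal-model components (4 x family variance, and total
    minus additive for the residual).
    """
    import pandas as pd

    df = pd.DataFrame({"y": y, "fam": family})
    sizes = df.groupby("fam").size()
    assert sizes.nunique() == 1, "oracle requires balanced families"
    k = int(sizes.iloc[0])
    n_fam = len(sizes)
    grand = df["y"].mean()
    means = df.groupby("fam")["y"].mean()
    msb = k * ((means - grand) ** 2).sum() / (n_fam - 1)
    msw = ((df["y"] - df["fam"].map(means)) ** 2).sum() / (n_fam * (k - 1))
    s2f = (msb - msw) / k
    s2a = 4.0 * s2f
    s2e = msw + s2f - s2a
    return float(s2a), float(s2e)
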