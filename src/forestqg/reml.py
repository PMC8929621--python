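"""Individual-tree mixed-model REML with pedigree or genomic kernels.

The univariate model is

    y = X b + Z_d d + Z_a a + e,   a ~ N(0, K s2_a),  d ~ N(0, I s2_d),
                                   e ~ N(0, I s2_e)

with K the numerator (A) or genomic (G) relationship matrix and b the
genetic-group (provenance) fixed effects.  The multivariate model treats
trait-site combinations as correlated responses with genetic covariance
Sigma_a (x) K (Kronecker product) and a residual covariance that is free
between responses measured on the same trees at the same site and
structurally zero across sites.

Estimation follows the EM algorithm on the restricted likelihood — variance
components updated from BLUP solutions and conditional covariances until the
largest relative change falls below tolerance — followed by a single
Average-Information (AI) step whose inverse provides asymptotic standard
errors.  The EM log-likelihood trace is checked to be non-decreasing.

Two computational routes produce identical results: a general dense route
that assembles the full N x N phenotypic covariance (needed for unbalanced
responses, cross-site layouts and random design effects), and a fast route
for balanced single-site layouts that diagonalizes K once and iterates on
t x t blocks per eigenvector.  The final likelihood, AI matrix, fixed-effect
solutions and BLUPs are always evaluated on the dense route at the converged
components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator

from .errors import NumericalError, StructuralError
from .pedigree import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "FitResult",
    "AnimalModelREML",
    "MultiTraitREML",
    "reml_loglik",
    "fit_univariate",
    "fit_multivariate",
    "predict_blup",
]

_EIG_CLIP = 1e-10  # PSD projection: clip eigenvalues below this fraction of the largest
_NEAR_ZERO = 1e-6  # boundary flag: component below this fraction of phenotypic variance


# ---------------------------------------------------------------------------
# model description and results
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Declarative description of a REML fit.

    ``responses`` is a list of ``(trait, site)`` pairs; ``site=None`` pools
    all sites for that trait.  Residual covariance is free between responses
    sharing the same site value and structurally zero otherwise.
    """

    responses: list[tuple[str, str | None]]
    groups: str | None = "group"
    replication: str | None = None
    relationship_source: str = "A"
    tol: float = 1e-8
    max_iter: int = 2000

    def response_names(self) -> list[str]:
        return [t if s is None else f"{t}@{s}" for t, s in self.responses]


@dataclass
class VarianceComponents:
    """REML variance-component estimates with their asymptotic covariance."""

    responses: list[str]
    sigma_a: np.ndarray  # r x r genetic covariance
    sigma_e: np.ndarray  # r x r residual covariance (structural zeros exact)
    structural_zero: np.ndarray  # r x r bool
    sigma_d: float | None = None
    param_names: list[str] = field(default_factory=list)
    asymptotic_covariance: np.ndarray | None = None

    def index_a(self, i: int, j: int) -> int:
        return self.param_names.index(f"sigma_a[{min(i, j)},{max(i, j)}]")

    def index_e(self, i: int, j: int) -> int:
        return self.param_names.index(f"sigma_e[{min(i, j)},{max(i, j)}]")

    def se(self, name: str) -> float:
        if self.asymptotic_covariance is None:
            return np.nan
        k = self.param_names.index(name)
        v = self.asymptotic_covariance[k, k]
        return float(np.sqrt(v)) if v >= 0 else np.nan


@dataclass
class FitResult:
    """Outcome of a REML fit: components, likelihood trace and BLUPs."""

    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    vc: VarianceComponents
    fixed_effects: pd.Series
    breeding_values: pd.DataFrame  # columns: response, id, blup, pev, accuracy
    flags: list[str]
    n_obs: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


# ---------------------------------------------------------------------------
# internal problem assembly
# ---------------------------------------------------------------------------


@dataclass
class _Resp:
    name: str
    trait: str
    site: str | None
    ids: list[str]
    y: np.ndarray
    X: np.ndarray
    x_labels: list[str]
    rep: np.ndarray | None
    rows: np.ndarray = None  # slice into the stacked observation vector
    kpos: np.ndarray = None  # positions of ids within the observed-union K


def _build_responses(
    data: pd.DataFrame, spec: ModelSpec
) -> list[_Resp]:
    out = []
    for (trait, site), name in zip(spec.responses, spec.response_names()):
        df = data if site is None else data[data["site"] == site]
        df = df[df[trait].notna()]
        if len(df) == 0:
            raise StructuralError(f"response {name!r} has zero observations")
        ids = [str(t) for t in df["tree"]]
        if len(set(ids)) != len(ids):
            raise StructuralError(f"response {name!r}: duplicated tree measurements")
        y = df[trait].to_numpy(dtype=float)
        if spec.groups is not None and spec.groups in df.columns:
            dummies = pd.get_dummies(df[spec.groups].astype(str), prefix=f"{name}:{spec.groups}")
            X = dummies.to_numpy(dtype=float)
            labels = list(dummies.columns)
        else:
            X = np.ones((len(df), 1))
            labels = [f"{name}:intercept"]
        rep = None
        if spec.replication is not None:
            rep = df[spec.replication].astype(str).to_numpy()
        out.append(_Resp(name, trait, site, ids, y, X, labels, rep))
    return out


def _check_rank(X: np.ndarray, labels: list[str]):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify aliased columns by greedy QR
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(labels[j])
        raise StructuralError(f"fixed effects rank deficient; aliased: {aliased}")


class _Problem:
    """Assembled REML problem over stacked observations."""

    def __init__(self, data, spec: ModelSpec, K: RelationshipMatrix, k_ridge=0.0):
        self.spec = spec
        self.resps = _build_responses(data, spec)
        self.r = len(self.resps)
        kid_set = set(K.ids)
        for resp in self.resps:
            missing = [i for i in resp.ids if i not in kid_set]
            if missing:
                raise StructuralError(
                    f"response {resp.name!r}: trees absent from relationship "
                    f"matrix: {missing[:5]}"
                )
        union: list[str] = []
        seen = set()
        for resp in self.resps:
            for i in resp.ids:
                if i not in seen:
                    seen.add(i)
                    union.append(i)
        self.obs_ids = union
        self.q = len(union)
        self.K_full = K
        self.Kq = K.subset(union).values
        if k_ridge:
            self.Kq = self.Kq + k_ridge * np.eye(self.q)
        upos = {i: k for k, i in enumerate(union)}
        pos = 0
        for resp in self.resps:
            resp.rows = np.arange(pos, pos + len(resp.y))
            resp.kpos = np.array([upos[i] for i in resp.ids], dtype=int)
            pos += len(resp.y)
        self.N = pos
        self.y = np.concatenate([resp.y for resp in self.resps])

        # fixed-effect design, block diagonal over responses
        p = sum(resp.X.shape[1] for resp in self.resps)
        X = np.zeros((self.N, p))
        labels = []
        col = 0
        for resp in self.resps:
            pc = resp.X.shape[1]
            X[resp.rows, col : col + pc] = resp.X
            labels += resp.x_labels
            col += pc
        _check_rank(X, labels)
        self.X = X
        self.x_labels = labels
        self.p = p

        # structural residual zeros: free iff same site value
        sz = np.zeros((self.r, self.r), dtype=bool)
        for i in range(self.r):
            for j in range(self.r):
                sz[i, j] = self.resps[i].site != self.resps[j].site
        np.fill_diagonal(sz, False)
        self.structural_zero = sz

        # shared-individual maps for free residual pairs
        self.shared: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for i in range(self.r):
            for j in range(i, self.r):
                if sz[i, j]:
                    continue
                if i == j:
                    n = len(self.resps[i].y)
                    self.shared[(i, i)] = (np.arange(n), np.arange(n))
                    continue
                pi = {t: k for k, t in enumerate(self.resps[i].ids)}
                ai, bj = [], []
                for k, t in enumerate(self.resps[j].ids):
                    if t in pi:
                        ai.append(pi[t])
                        bj.append(k)
                self.shared[(i, j)] = (np.array(ai, dtype=int), np.array(bj, dtype=int))

        # random design effect
        self.Zd = None
        if spec.replication is not None:
            reps = np.concatenate(
                [resp.rep for resp in self.resps if resp.rep is not None]
            )
            if len(reps) != self.N:
                raise StructuralError("replication labels missing for some responses")
            dummies = pd.get_dummies(pd.Series(reps))
            self.Zd = dummies.to_numpy(dtype=float)
            self.m_d = self.Zd.shape[1]

        self.phen_scale = float(np.var(self.y)) or 1.0

    # -- dense covariance assembly ------------------------------------------

    def assemble_V(self, vc: VarianceComponents) -> np.ndarray:
        V = np.zeros((self.N, self.N))
        for i in range(self.r):
            ri = self.resps[i]
            for j in range(self.r):
                s = vc.sigma_a[i, j]
                if s != 0.0:
                    rj = self.resps[j]
                    V[np.ix_(ri.rows, rj.rows)] += s * self.Kq[
                        np.ix_(ri.kpos, rj.kpos)
                    ]
        for (i, j), (ai, bj) in self.shared.items():
            s = vc.sigma_e[i, j]
            if s == 0.0:
                continue
            ra, rb = self.resps[i].rows[ai], self.resps[j].rows[bj]
            V[ra, rb] += s
            if i != j:
                V[rb, ra] += s
        if self.Zd is not None and vc.sigma_d:
            V += vc.sigma_d * (self.Zd @ self.Zd.T)
        return V

    def _P_and_logdet(self, V):
        try:
            c, low = sla.cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * float(np.mean(np.diag(V)))
            c, low = sla.cho_factor(V + jitter * np.eye(self.N), lower=True)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = sla.cho_solve((c, low), np.eye(self.N))
        VinvX = Vinv @ self.X
        XtVinvX = self.X.T @ VinvX
        sign, logdetX = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            raise NumericalError("X'V^-1X not positive definite")
        B = sla.solve(XtVinvX, VinvX.T, assume_a="pos")
        P = Vinv - VinvX @ B
        return P, Vinv, VinvX, XtVinvX, logdetV + logdetX

    def loglik_at(self, vc: VarianceComponents) -> float:
        V = self.assemble_V(vc)
        P, *_, logdet = self._P_and_logdet(V)
        Py = P @ self.y
        return -0.5 * (logdet + float(self.y @ Py))

    # -- one dense EM iteration ---------------------------------------------

    def em_step(self, vc: VarianceComponents):
        V = self.assemble_V(vc)
        P, Vinv, VinvX, XtVinvX, logdet = self._P_and_logdet(V)
        Py = P @ self.y
        ll = -0.5 * (logdet + float(self.y @ Py))

        # genetic update:  Sa' = Sa + Sa (S'KS - T) Sa / q
        S = np.zeros((self.q, self.r))
        for l, resp in enumerate(self.resps):
            np.add.at(S[:, l], resp.kpos, Py[resp.rows])
        StKS = S.T @ self.Kq @ S
        T = np.empty((self.r, self.r))
        for i in range(self.r):
            ri = self.resps[i]
            for j in range(i, self.r):
                rj = self.resps[j]
                Pb = P[np.ix_(ri.rows, rj.rows)]
                Kb = self.Kq[np.ix_(ri.kpos, rj.kpos)]
                T[i, j] = T[j, i] = float(np.sum(Pb * Kb))
        Sa = vc.sigma_a
        Sa_new = Sa + Sa @ (StKS - T) @ Sa / self.q
        Sa_new = _psd_project(0.5 * (Sa_new + Sa_new.T))

        # residual update on jointly observed individuals
        R = np.zeros((self.N, self.N))
        for (i, j), (ai, bj) in self.shared.items():
            s = vc.sigma_e[i, j]
            if s == 0.0:
                continue
            ra, rb = self.resps[i].rows[ai], self.resps[j].rows[bj]
            R[ra, rb] += s
            if i != j:
                R[rb, ra] += s
        e_hat = R @ Py
        RPR = R @ P @ R
        Se_new = np.zeros_like(vc.sigma_e)
        for (i, j), (ai, bj) in self.shared.items():
            ra, rb = self.resps[i].rows[ai], self.resps[j].rows[bj]
            n_sh = len(ai)
            if n_sh == 0:
                Se_new[i, j] = Se_new[j, i] = vc.sigma_e[i, j]
                continue
            cross = float(e_hat[ra] @ e_hat[rb])
            trace = float(
                n_sh * vc.sigma_e[i, j] - np.sum(RPR[ra, rb])
            )
            Se_new[i, j] = Se_new[j, i] = (cross + trace) / n_sh
        Se_new = _project_residual(Se_new, self.structural_zero)

        sd_new = vc.sigma_d
        if self.Zd is not None:
            sd = vc.sigma_d
            d_hat = sd * (self.Zd.T @ Py)
            PZ = P @ self.Zd
            tr = float(np.sum(self.Zd * PZ))
            sd_new = (float(d_hat @ d_hat) + sd * self.m_d - sd**2 * tr) / self.m_d
            sd_new = max(sd_new, 0.0)

        return ll, Sa_new, Se_new, sd_new

    # -- finalization at converged components --------------------------------

    def finalize(self, vc: VarianceComponents):
        V = self.assemble_V(vc)
        P, Vinv, VinvX, XtVinvX, logdet = self._P_and_logdet(V)
        Py = P @ self.y
        ll = -0.5 * (logdet + float(self.y @ Py))

        beta = sla.solve(XtVinvX, self.X.T @ (Vinv @ self.y), assume_a="pos")
        fixed = pd.Series(beta, index=self.x_labels, name="estimate")

        # AI matrix over the free parameters
        names, U = [], []
        for i in range(self.r):
            for j in range(i, self.r):
                u = np.zeros(self.N)
                ri, rj = self.resps[i], self.resps[j]
                u[ri.rows] += self.Kq[np.ix_(ri.kpos, rj.kpos)] @ Py[rj.rows]
                if i != j:
                    u[rj.rows] += self.Kq[np.ix_(rj.kpos, ri.kpos)] @ Py[ri.rows]
                names.append(f"sigma_a[{i},{j}]")
                U.append(u)
        for (i, j), (ai, bj) in sorted(self.shared.items()):
            u = np.zeros(self.N)
            ra, rb = self.resps[i].rows[ai], self.resps[j].rows[bj]
            u[ra] += Py[rb]
            if i != j:
                u[rb] += Py[ra]
            names.append(f"sigma_e[{i},{j}]")
            U.append(u)
        if self.Zd is not None:
            U.append(self.Zd @ (self.Zd.T @ Py))
            names.append("sigma_d")
        Umat = np.column_stack(U)
        AI = 0.5 * (Umat.T @ (P @ Umat))
        try:
            acov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            acov = np.linalg.pinv(AI)
        vc.param_names = names
        vc.asymptotic_covariance = acov

        blups = self._blups(vc, P, Py)
        return ll, fixed, blups

    def _blups(self, vc: VarianceComponents, P, Py):
        Kf = self.K_full
        glob = Kf.indices(self.obs_ids)
        KX = Kf.values[:, glob]  # n_all x q
        rows = []
        diagK = np.diag(Kf.values)
        Pyq = np.zeros((self.q, self.r))
        for l, resp in enumerate(self.resps):
            np.add.at(Pyq[:, l], resp.kpos, Py[resp.rows])
        # weights per response: w_r = Sigma_a[r, :] broadcast on response blocks
        for ridx in range(self.r):
            w = np.zeros(self.N)
            for l, resp in enumerate(self.resps):
                w[resp.rows] = vc.sigma_a[ridx, l]
            a_hat = KX @ (Pyq @ vc.sigma_a[ridx])
            # PEV: Sa_rr * K_ii - diag(C P C') with C row i = sum_l Sa[r,l] K[i, kpos_l scattered]
            C = np.zeros((Kf.values.shape[0], self.N))
            for l, resp in enumerate(self.resps):
                C[:, resp.rows] = vc.sigma_a[ridx, l] * KX[:, resp.kpos]
            CP = C @ P
            pev = vc.sigma_a[ridx, ridx] * diagK - np.einsum("ij,ij->i", CP, C)
            pev = np.clip(pev, 0.0, None)
            denom = diagK * vc.sigma_a[ridx, ridx]
            with np.errstate(divide="ignore", invalid="ignore"):
                acc = np.sqrt(np.clip(1.0 - pev / np.where(denom > 0, denom, np.nan), 0.0, 1.0))
            rows.append(
                pd.DataFrame(
                    {
                        "response": vc.responses[ridx],
                        "id": Kf.ids,
                        "blup": a_hat,
                        "pev": pev,
                        "accuracy": acc,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    # -- fast (eigen) route --------------------------------------------------

    def fast_route_available(self) -> bool:
        if self.Zd is not None:
            return False
        if self.structural_zero.any():
            return False
        first = self.resps[0].ids
        return all(resp.ids == first for resp in self.resps)

    def fast_em(self, Sa, Se, tol, max_iter):
        n, t = self.q, self.r
        w, Uk = np.linalg.eigh(self.Kq)
        w = np.clip(w, 1e-12, None)
        Y = np.column_stack([resp.y for resp in self.resps])
        Yt = Uk.T @ Y
        X0 = self.resps[0].X
        # responses may have different dummy encodings; require identical
        for resp in self.resps:
            if resp.X.shape != X0.shape or not np.allclose(resp.X, X0):
                return None
        X0t = Uk.T @ X0
        g = X0.shape[1]
        trace = []
        converged = False
        prev = _pack(Sa, Se, None, self.structural_zero)
        it = 0
        for it in range(1, max_iter + 1):
            Vb = w[:, None, None] * Sa[None] + Se[None]
            Vinv = np.linalg.inv(Vb)
            sign, ld = np.linalg.slogdet(Vb)
            if np.any(sign <= 0):
                raise NumericalError("non-PD covariance block in fast route")
            logdetV = float(ld.sum())
            # B[(r,a),(s,b)] = sum_j Vinv[j,r,s] X0t[j,a] X0t[j,b]
            B = np.einsum("jrs,ja,jb->rasb", Vinv, X0t, X0t).reshape(t * g, t * g)
            VinvY = np.einsum("jrs,js->jr", Vinv, Yt)
            c = np.einsum("jr,ja->ra", VinvY, X0t).reshape(t * g)
            sign, logdetB = np.linalg.slogdet(B)
            if sign <= 0:
                raise NumericalError("X'V^-1X not positive definite")
            beta = sla.solve(B, c, assume_a="pos").reshape(t, g)
            F = X0t @ beta.T  # n x t fitted values
            Pyt = np.einsum("jrs,js->jr", Vinv, Yt - F)
            ypy = float(np.sum((Yt - F) * Pyt))
            ll = -0.5 * (logdetV + logdetB + ypy)
            trace.append(ll)

            # P_jj = Vinv_j - A_j Binv A_j',  A_j[r,(s,a)] = Vinv[j,r,s] X0t[j,a]
            Binv = np.linalg.inv(B).reshape(t, g, t, g)
            # correction term per eigen block, contracted with weights 1 and w
            corr = np.einsum(
                "jrs,ja,savb,juv,jb->jru", Vinv, X0t, Binv, Vinv, X0t, optimize=True
            )
            Pjj = Vinv - corr
            W1 = np.einsum("j,jr,js->rs", w, Pyt, Pyt)
            W2 = np.einsum("j,jrs->rs", w, Pjj)
            E1 = np.einsum("jr,js->rs", Pyt, Pyt)
            E2 = Pjj.sum(axis=0)
            Sa_new = _psd_project(Sa + Sa @ (W1 - W2) @ Sa / n)
            Se_new = _psd_project(Se + Se @ (E1 - E2) @ Se / n)
            cur = _pack(Sa_new, Se_new, None, self.structural_zero)
            delta = _rel_change(prev, cur, self.phen_scale)
            Sa, Se = Sa_new, Se_new
            prev = cur
            if delta < tol:
                converged = True
                break
        return Sa, Se, trace, converged, it


# ---------------------------------------------------------------------------
# numerics helpers
# ---------------------------------------------------------------------------


def _psd_project(M: np.ndarray) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    floor = max(w[-1], 0.0) * _EIG_CLIP
    if w[0] >= floor:
        return M
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


def _project_residual(Se: np.ndarray, zero_mask: np.ndarray) -> np.ndarray:
    """PSD-project residual covariance blockwise, keeping structural zeros."""
    out = np.zeros_like(Se)
    r = Se.shape[0]
    unseen = set(range(r))
    while unseen:
        i = min(unseen)
        block = [j for j in range(r) if not zero_mask[i, j] and j in unseen]
        idx = np.array(block)
        out[np.ix_(idx, idx)] = _psd_project(Se[np.ix_(idx, idx)])
        unseen -= set(block)
    return out


def _unpack(theta, r, zero_mask, has_sd):
    Sa = np.zeros((r, r))
    k = 0
    for i in range(r):
        for j in range(i, r):
            Sa[i, j] = Sa[j, i] = theta[k]
            k += 1
    Se = np.zeros((r, r))
    for i in range(r):
        for j in range(i, r):
            if not zero_mask[i, j]:
                Se[i, j] = Se[j, i] = theta[k]
                k += 1
    sd = None
    if has_sd:
        sd = max(float(theta[k]), 0.0)
    return _psd_project(Sa), _project_residual(Se, zero_mask), sd


def _pack(Sa, Se, sd, zero_mask):
    r = Sa.shape[0]
    vals = []
    for i in range(r):
        for j in range(i, r):
            vals.append(Sa[i, j])
    for i in range(r):
        for j in range(i, r):
            if not zero_mask[i, j]:
                vals.append(Se[i, j])
    if sd is not None:
        vals.append(sd)
    return np.array(vals)


def _rel_change(prev, cur, scale):
    denom = np.maximum(np.maximum(np.abs(prev), np.abs(cur)), _NEAR_ZERO * scale)
    keep = np.maximum(np.abs(prev), np.abs(cur)) > 1e-8 * scale
    if not keep.any():
        return 0.0
    return float(np.max(np.abs(cur - prev)[keep] / denom[keep]))


# ---------------------------------------------------------------------------
# fitting driver
# ---------------------------------------------------------------------------


def _dense_em(prob: "_Problem", names, Sa, Se, sd, tol, max_iter):
    """EM on the dense route with safeguarded extrapolation.

    Each cycle runs two plain EM steps and proposes a SQUAREM-style
    extrapolated point; the proposal is accepted only when its restricted
    likelihood is at least that of the second EM step, so the recorded
    log-likelihood trace remains non-decreasing.
    """

    def make(Sa, Se, sd):
        return VarianceComponents(
            responses=names,
            sigma_a=Sa,
            sigma_e=Se,
            structural_zero=prob.structural_zero,
            sigma_d=sd,
        )

    zero = prob.structural_zero
    has_sd = sd is not None
    r = Sa.shape[0]
    trace: list[float] = []
    converged = False
    n_iter = 0
    vc = make(Sa, Se, sd)
    while n_iter < max_iter:
        ll0, Sa1, Se1, sd1 = prob.em_step(vc)
        n_iter += 1
        trace.append(ll0)
        vc1 = make(Sa1, Se1, sd1)
        th0 = _pack(vc.sigma_a, vc.sigma_e, vc.sigma_d, zero)
        th1 = _pack(Sa1, Se1, sd1, zero)
        if _rel_change(th0, th1, prob.phen_scale) < tol:
            vc = vc1
            converged = True
            break
        ll1, Sa2, Se2, sd2 = prob.em_step(vc1)
        n_iter += 1
        trace.append(ll1)
        vc2 = make(Sa2, Se2, sd2)
        th2 = _pack(Sa2, Se2, sd2, zero)
        if _rel_change(th1, th2, prob.phen_scale) < tol:
            vc = vc2
            converged = True
            break
        step = th1 - th0
        curv = (th2 - th1) - step
        nv = float(np.linalg.norm(curv))
        vc_next = vc2
        if nv > 1e-14:
            alpha = -float(np.linalg.norm(step)) / nv
            alpha = min(alpha, -1.0)
            th_acc = th0 - 2.0 * alpha * step + alpha**2 * curv
            vc_acc = make(*_unpack(th_acc, r, zero, has_sd))
            try:
                ll2 = prob.loglik_at(vc2)
                ll_acc = prob.loglik_at(vc_acc)
                if np.isfinite(ll_acc) and ll_acc >= ll2:
                    vc_next = vc_acc
            except (np.linalg.LinAlgError, NumericalError):
                pass
        vc = vc_next
    return vc.sigma_a, vc.sigma_e, vc.sigma_d, trace, converged, n_iter


def _run_fit(data, spec: ModelSpec, K: RelationshipMatrix, k_ridge=0.0) -> FitResult:
    prob = _Problem(data, spec, K, k_ridge=k_ridge)
    r = prob.r
    names = spec.response_names()

    # starting values: half the phenotypic (co)variance, diagonal loaded
    Y = np.full((prob.q, r), np.nan)
    upos = {i: k for k, i in enumerate(prob.obs_ids)}
    for l, resp in enumerate(prob.resps):
        Y[resp.kpos, l] = resp.y
    C = pd.DataFrame(Y).cov().to_numpy()
    C = np.where(np.isnan(C), 0.0, C)
    C = C + 0.1 * np.mean(np.diag(C)) * np.eye(r)
    Sa = _psd_project(0.5 * C)
    Se = _project_residual(
        np.where(prob.structural_zero, 0.0, 0.5 * C), prob.structural_zero
    )
    sd = None
    if prob.Zd is not None:
        sd = 0.1 * float(np.mean(np.diag(C)))

    trace: list[float] = []
    flags: list[str] = []
    converged = False
    n_iter = 0

    if prob.fast_route_available():
        fast = prob.fast_em(Sa, Se, spec.tol, spec.max_iter)
    else:
        fast = None
    if fast is not None:
        Sa, Se, trace, converged, n_iter = fast
    else:
        Sa, Se, sd, trace, converged, n_iter = _dense_em(
            prob, names, Sa, Se, sd, spec.tol, spec.max_iter
        )

    trace = np.asarray(trace)
    drops = np.diff(trace) < -1e-8 * np.maximum(1.0, np.abs(trace[:-1]))
    if drops.any():
        raise NumericalError(
            f"EM log-likelihood decreased at iteration(s) {np.flatnonzero(drops) + 1}"
        )
    if not converged:
        flags.append("unconverged")
        warnings.warn(
            f"EM did not converge in {spec.max_iter} iterations", stacklevel=2
        )

    vc = VarianceComponents(
        responses=names,
        sigma_a=Sa,
        sigma_e=Se,
        structural_zero=prob.structural_zero,
        sigma_d=sd,
    )
    for i in range(r):
        if Sa[i, i] < _NEAR_ZERO * prob.phen_scale:
            flags.append(f"near-zero genetic variance: {names[i]}")

    ll, fixed, blups = prob.finalize(vc)
    trace = np.append(trace, ll) if len(trace) == 0 or ll >= trace[-1] - 1e-6 else trace
    return FitResult(
        converged=converged,
        n_iter=n_iter,
        loglik_trace=trace,
        vc=vc,
        fixed_effects=fixed,
        breeding_values=blups,
        flags=flags,
        n_obs=prob.N,
    )


# ---------------------------------------------------------------------------
# public functional interface
# ---------------------------------------------------------------------------


def reml_loglik(
    spec: ModelSpec,
    data: pd.DataFrame,
    K: RelationshipMatrix,
    vc: VarianceComponents,
) -> float:
    """Restricted log-likelihood at fixed variance components.

    Returns -0.5 [log|V| + log|X'V^-1 X| + y'Py] up to an additive constant.
    """
    prob = _Problem(data, spec, K)
    return prob.loglik_at(vc)


def fit_univariate(
    spec: ModelSpec, data: pd.DataFrame, K: RelationshipMatrix
) -> FitResult:
    if len(spec.responses) != 1:
        raise StructuralError("univariate fit requires exactly one response")
    return _run_fit(data, spec, K)


def fit_multivariate(
    spec: ModelSpec, data: pd.DataFrame, K: RelationshipMatrix
) -> FitResult:
    if len(spec.responses) < 2:
        raise StructuralError("multivariate fit requires >= 2 responses")
    return _run_fit(data, spec, K)


def predict_blup(fit: FitResult) -> pd.DataFrame:
    """Breeding values with prediction-error variances and accuracies."""
    return fit.breeding_values.copy()


def blup_at(
    spec: ModelSpec,
    data: pd.DataFrame,
    K: RelationshipMatrix,
    vc: VarianceComponents,
) -> pd.DataFrame:
    """BLUP solutions of the mixed-model equations at fixed components."""
    prob = _Problem(data, spec, K)
    _, _, blups = prob.finalize(vc)
    return blups


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------


class AnimalModelREML(BaseEstimator):
    """Univariate individual-tree mixed model fitted by EM-REML.

    Parameters
    ----------
    response : str
        Trait column to analyse.
    site : str, optional
        Restrict to one site; ``None`` pools all rows.
    groups : str, optional
        Column holding the genetic-group fixed effect (``None`` = intercept).
    replication : str, optional
        Column holding a random design effect; ``None`` when the data were
        pre-adjusted for replication.
    tol, max_iter
        EM convergence controls (largest relative component change).
    k_ridge : float
        Diagonal loading applied to the relationship matrix before inversion.

    Attributes
    ----------
    sigma_a_, sigma_e_, sigma_d_ : float
        Variance-component estimates.
    heritability_, heritability_se_ : float
        h2 = sigma_a / (sigma_a + sigma_e) with its delta-method SE.
    breeding_values_ : pandas.DataFrame
        BLUPs with prediction-error variance and accuracy for every
        individual of the relationship matrix.
    result_ : FitResult
        Full fit record (components, SEs, likelihood trace, flags).
    """

    def __init__(
        self,
        response: str = "trait",
        site: str | None = None,
        groups: str | None = "group",
        replication: str | None = None,
        tol: float = 1e-8,
        max_iter: int = 2000,
        k_ridge: float = 0.0,
    ):
        self.response = response
        self.site = site
        self.groups = groups
        self.replication = replication
        self.tol = tol
        self.max_iter = max_iter
        self.k_ridge = k_ridge

    def fit(self, data: pd.DataFrame, relationship: RelationshipMatrix):
        spec = ModelSpec(
            responses=[(self.response, self.site)],
            groups=self.groups,
            replication=self.replication,
            relationship_source=relationship.kind,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        res = _run_fit(data, spec, relationship, k_ridge=self.k_ridge)
        self.result_ = res
        self.sigma_a_ = float(res.vc.sigma_a[0, 0])
        self.sigma_e_ = float(res.vc.sigma_e[0, 0])
        self.sigma_d_ = res.vc.sigma_d
        from .report import heritability

        h2, se = heritability(res.vc, res.vc.responses[0])
        self.heritability_ = h2
        self.heritability_se_ = se
        self.loglik_trace_ = res.loglik_trace
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.fixed_effects_ = res.fixed_effects
        self.breeding_values_ = res.breeding_values
        return self

    def predict(self, ids=None) -> pd.Series:
        """Predicted breeding values, optionally for a subset of ids."""
        bv = self.breeding_values_.set_index("id")["blup"]
        return bv if ids is None else bv.loc[[str(i) for i in ids]]


class MultiTraitREML(BaseEstimator):
    """Multivariate individual-tree mixed model (traits and/or sites).

    ``responses`` is a list of ``(trait, site)`` pairs; measurements from
    different sites are treated as different traits with genetic covariance
    Sigma_a (x) K and zero residual covariance across sites.

    Attributes (after fit): ``sigma_a_`` and ``sigma_e_`` covariance matrices,
    ``responses_`` names, ``genetic_correlations_`` DataFrame and ``result_``.
    """

    def __init__(
        self,
        responses=None,
        groups: str | None = "group",
        tol: float = 1e-8,
        max_iter: int = 2000,
        k_ridge: float = 0.0,
    ):
        self.responses = responses
        self.groups = groups
        self.tol = tol
        self.max_iter = max_iter
        self.k_ridge = k_ridge

    def fit(self, data: pd.DataFrame, relationship: RelationshipMatrix):
        spec = ModelSpec(
            responses=list(self.responses),
            groups=self.groups,
            relationship_source=relationship.kind,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        res = _run_fit(data, spec, relationship, k_ridge=self.k_ridge)
        self.result_ = res
        self.sigma_a_ = res.vc.sigma_a
        self.sigma_e_ = res.vc.sigma_e
        self.responses_ = res.vc.responses
        self.loglik_trace_ = res.loglik_trace
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        from .report import genetic_correlation

        rows = []
        r = len(self.responses_)
        for i in range(r):
            for j in range(i + 1, r):
                ra, se = genetic_correlation(res.vc, (i, j))
                rows.append(
                    {
                        "response_i": self.responses_[i],
                        "response_j": self.responses_[j],
                        "r_a": ra,
                        "se": se,
                    }
                )
        self.genetic_correlations_ = pd.DataFrame(rows)
        return self

    def predict(self, ids=None) -> pd.DataFrame:
        bv = self.result_.breeding_values
        if ids is None:
            return bv.copy()
        ids = [str(i) for i in ids]
        return bv[bv["id"].isin(ids)].copy()
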