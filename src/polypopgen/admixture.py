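"""Bayesian admixture clustering of dominant (binary band) data.

A STRUCTURE-style Gibbs sampler under the admixture model with correlated
allele frequencies: each band is treated as a haploid biallelic locus;
cluster band frequencies p_kl follow the Beta F-model around ancestral
frequencies, individual admixture proportions q_i follow a symmetric
Dirichlet(alpha) with alpha updated by a Metropolis step. Model choice uses
the Evanno delta-K second-difference criterion over replicate runs, and
replicates are aligned with a CLUMPP-style Greedy column permutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _perms

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment

from .genotypes import DominantMatrix

__all__ = [
    "McmcSettings",
    "QMatrix",
    "run_admixture",
    "admixture_scan",
    "evanno",
    "align_runs",
]


@dataclass
class McmcSettings:
    """MCMC run configuration.

    Defaults are desk-scale (20 000 sweeps, 5 000 burn-in, 3 replicates);
    full-scale settings (500 000 / 50 000 / 10 replicates, K 1-10) are a
    matter of passing larger numbers.
    """

    reps: int = 20_000
    burnin: int = 5_000
    replicates: int = 3
    k_range: tuple[int, int] = (1, 10)
    seed: int = 0
    thin: int = 10  # lnP trace thinning

    def __post_init__(self) -> None:
        if self.burnin >= self.reps:
            raise ValueError("burnin must be smaller than reps")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.k_range[0] < 1 or self.k_range[0] > self.k_range[1]:
            raise ValueError("invalid k_range")


@dataclass
class QMatrix:
    individuals: list[str]
    q: np.ndarray  # individuals x K posterior mean memberships
    lnP: np.ndarray  # thinned log-likelihood trace
    mean_lnP: float  # model log-evidence estimate: mean - var/2 of the trace
    K: int
    seed: int

    def __post_init__(self) -> None:
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("q rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.q, index=self.individuals, columns=[f"cluster_{k+1}" for k in range(self.K)]
        )

    def hard_labels(self) -> np.ndarray:
        return self.q.argmax(axis=1)


@njit(cache=True)
def _gibbs_kernel(x, obs, pbar, K, reps, burnin, thin, seed):  # pragma: no cover
    np.random.seed(seed)
    N, L = x.shape
    p = np.empty((K, L))
    for k in range(K):
        for l in range(L):
            p[k, l] = min(max(pbar[l] + 0.05 * (np.random.rand() - 0.5), 0.01), 0.99)
    q = np.full((N, K), 1.0 / K)
    F = np.full(K, 0.1)
    alpha = 1.0
    qsum = np.zeros((N, K))
    n_kept = 0
    n_tr = reps // thin
    trace = np.empty(n_tr)
    tr = 0
    probs = np.empty(K)
    n1 = np.empty((K, L))
    n0 = np.empty((K, L))
    m = np.empty((N, K))

    for it in range(reps):
        # --- latent cluster-of-origin indicators, accumulated into counts
        n1[:] = 0.0
        n0[:] = 0.0
        m[:] = 0.0
        for i in range(N):
            for l in range(L):
                if not obs[i, l]:
                    continue
                tot = 0.0
                for k in range(K):
                    pr = q[i, k] * (p[k, l] if x[i, l] == 1 else 1.0 - p[k, l])
                    probs[k] = pr
                    tot += pr
                u = np.random.rand() * tot
                acc = 0.0
                kk = K - 1
                for k in range(K):
                    acc += probs[k]
                    if u <= acc:
                        kk = k
                        break
                m[i, kk] += 1.0
                if x[i, l] == 1:
                    n1[kk, l] += 1.0
                else:
                    n0[kk, l] += 1.0

        # --- band frequencies under the Beta F-model prior
        for k in range(K):
            fk = F[k]
            lam = (1.0 - fk) / fk
            for l in range(L):
                a = pbar[l] * lam + n1[k, l]
                b = (1.0 - pbar[l]) * lam + n0[k, l]
                v = np.random.beta(a, b)
                p[k, l] = min(max(v, 1e-6), 1.0 - 1e-6)

        # --- admixture proportions
        for i in range(N):
            tot = 0.0
            for k in range(K):
                g = np.random.gamma(alpha + m[i, k], 1.0)
                if g < 1e-300:
                    g = 1e-300
                q[i, k] = g
                tot += g
            for k in range(K):
                q[i, k] /= tot

        # --- alpha Metropolis (uniform(0,10) prior, shared across clusters)
        if K > 1:
            prop = alpha + 0.25 * np.random.randn()
            if 0.001 < prop < 10.0:
                slq = 0.0
                for i in range(N):
                    for k in range(K):
                        slq += math.log(q[i, k])
                cur = N * (math.lgamma(K * alpha) - K * math.lgamma(alpha)) + (alpha - 1.0) * slq
                new = N * (math.lgamma(K * prop) - K * math.lgamma(prop)) + (prop - 1.0) * slq
                if math.log(np.random.rand() + 1e-300) < new - cur:
                    alpha = prop

        # --- F_k Metropolis (uniform(0,1) prior)
        for k in range(K):
            prop = F[k] + 0.05 * np.random.randn()
            if not (0.001 < prop < 0.999):
                continue
            cur = 0.0
            new = 0.0
            lam_c = (1.0 - F[k]) / F[k]
            lam_n = (1.0 - prop) / prop
            for l in range(L):
                ac, bc = pbar[l] * lam_c, (1.0 - pbar[l]) * lam_c
                an, bn = pbar[l] * lam_n, (1.0 - pbar[l]) * lam_n
                lp = math.log(p[k, l])
                l1p = math.log(1.0 - p[k, l])
                cur += math.lgamma(ac + bc) - math.lgamma(ac) - math.lgamma(bc) + (ac - 1) * lp + (bc - 1) * l1p
                new += math.lgamma(an + bn) - math.lgamma(an) - math.lgamma(bn) + (an - 1) * lp + (bn - 1) * l1p
            if math.log(np.random.rand() + 1e-300) < new - cur:
                F[k] = prop

        # --- bookkeeping
        if it >= burnin:
            qsum += q
            n_kept += 1
        if it % thin == 0 and tr < n_tr:
            ll = 0.0
            for i in range(N):
                for l in range(L):
                    if not obs[i, l]:
                        continue
                    s = 0.0
                    for k in range(K):
                        s += q[i, k] * (p[k, l] if x[i, l] == 1 else 1.0 - p[k, l])
                    ll += math.log(s + 1e-300)
            trace[tr] = ll
            tr += 1

    return qsum / n_kept, trace[:tr]


def run_admixture(dm: DominantMatrix, K: int, settings: McmcSettings | None = None, seed: int | None = None) -> QMatrix:
    """One MCMC run at a fixed K; returns the posterior-mean Q matrix.

    Reproducible given the seed. The lnP trace is thinned; mean_lnP averages
    the post-burn-in portion of the trace.
    """
    settings = settings or McmcSettings()
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(dm.individuals):
        raise ValueError("K cannot exceed the number of individuals")
    all_missing = dm.missing.all(axis=1)
    if all_missing.any():
        bad = [dm.individuals[i] for i in np.where(all_missing)[0]]
        raise ValueError(f"individuals with no scored band: {bad}")
    x = dm.values.astype(np.int8)
    obs = ~dm.missing
    with np.errstate(invalid="ignore"):
        pbar = np.where(obs, x, np.nan)
        pbar = np.nanmean(pbar, axis=0)
    pbar = np.clip(np.nan_to_num(pbar, nan=0.5), 0.01, 0.99)
    seed = settings.seed if seed is None else seed
    q, trace = _gibbs_kernel(
        x, obs, pbar.astype(np.float64), K,
        settings.reps, settings.burnin, settings.thin, seed % (2**31 - 1),
    )
    post = trace[settings.burnin // settings.thin:]
    if not len(post):
        post = trace
    # harmonic-style model evidence estimate: mean - var/2 of the post-burn-in
    # likelihood trace (flattens, then falls, once K exceeds the true value)
    mean_lnp = float(post.mean() - post.var(ddof=1) / 2.0) if len(post) > 1 else float(post.mean())
    return QMatrix(
        individuals=list(dm.individuals),
        q=q / q.sum(axis=1, keepdims=True),
        lnP=trace,
        mean_lnP=mean_lnp,
        K=K,
        seed=seed,
    )


def admixture_scan(dm: DominantMatrix, settings: McmcSettings | None = None) -> dict[int, list[QMatrix]]:
    """Replicate runs over the configured K range; seeds derived per (K, replicate)."""
    settings = settings or McmcSettings()
    out: dict[int, list[QMatrix]] = {}
    for K in range(settings.k_range[0], settings.k_range[1] + 1):
        out[K] = [
            run_admixture(dm, K, settings, seed=(settings.seed + 1000 * K + r) % (2**31 - 1))
            for r in range(settings.replicates)
        ]
    return out


def evanno(lnp_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno delta-K table from replicate mean log-likelihoods per K.

    delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)), defined for interior K
    with at least two replicates; the best K maximises delta K. K values with
    zero replicate sd get a NaN delta K (flagged by the caller).
    """
    ks = sorted(lnp_by_k)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    mean = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnp_by_k[k], ddof=1)) if len(lnp_by_k[k]) > 1 else float("nan") for k in ks}
    rows = []
    for k in ks:
        lp = mean.get(k + 1)
        lm = mean.get(k - 1)
        d1 = mean[k] - lm if lm is not None else np.nan
        d2 = abs(lp - 2 * mean[k] + lm) if (lp is not None and lm is not None) else np.nan
        dk = d2 / sd[k] if (not np.isnan(d2) and sd[k] > 0) else np.nan
        rows.append({"K": k, "mean_lnP": mean[k], "sd_lnP": sd[k], "L1": d1, "L2_abs": d2, "delta_k": dk})
    df = pd.DataFrame(rows).set_index("K")
    interior = df["delta_k"].dropna()
    df.attrs["best_k"] = int(interior.idxmax()) if len(interior) else None
    return df


def evanno_from_runs(runs: dict[int, list[QMatrix]]) -> pd.DataFrame:
    return evanno({k: [r.mean_lnP for r in v] for k, v in runs.items()})


# ---------------------------------------------------------------------------
# CLUMPP-style Greedy alignment
# ---------------------------------------------------------------------------

def _best_permutation(ref: np.ndarray, q: np.ndarray) -> tuple:
    """Column order of q minimising squared Frobenius distance to ref."""
    K = q.shape[1]
    if K <= 8:
        best, best_d = None, np.inf
        for perm in _perms(range(K)):
            d = float(((ref - q[:, perm]) ** 2).sum())
            if d < best_d:
                best, best_d = perm, d
        return best
    # assignment relaxation: cost = squared distance between columns
    cost = ((ref[:, :, None] - q[:, None, :]) ** 2).sum(axis=0)
    _, cols = linear_sum_assignment(cost)
    return tuple(int(c) for c in cols)


def align_runs(runs: list[QMatrix]) -> tuple[QMatrix, float]:
    """Greedy alignment of replicate runs at the same K.

    Run 1 is the reference; each subsequent run is column-permuted to
    minimise the squared Frobenius distance to the running mean, then
    averaged. Returns the consensus QMatrix and the mean pairwise similarity
    G = 1 - ||Qa - Qb||_F / sqrt(2N) over aligned run pairs.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    inds = runs[0].individuals
    for r in runs:
        if r.K != K or r.individuals != inds:
            raise ValueError("runs must share K and individual order")
    aligned = [runs[0].q]
    for r in runs[1:]:
        ref = np.mean(aligned, axis=0)
        perm = _best_permutation(ref, r.q)
        aligned.append(r.q[:, perm])
    consensus = np.mean(aligned, axis=0)
    consensus /= consensus.sum(axis=1, keepdims=True)
    n = len(inds)
    sims = []
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            sims.append(1.0 - np.linalg.norm(aligned[i] - aligned[j]) / math.sqrt(2 * n))
    sim = float(np.mean(sims)) if sims else 1.0
    out = QMatrix(
        individuals=list(inds),
        q=consensus,
        lnP=np.concatenate([r.lnP for r in runs]),
        mean_lnP=float(np.mean([r.mean_lnP for r in runs])),
        K=K,
        seed=runs[0].seed,
    )
    return out, sim
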