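"""Isolation-by-distance inference.

Standard, stratified and partial Mantel tests to discriminate a hierarchical
island model (HIM, cluster-driven differentiation) from a stepping-stone
model (SSM, distance-driven gene flow), plus beta-regression models of
genetic distance on geographic distance and barrier covariates compared by
AIC and pseudo-R2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from statsmodels.othermod.betareg import BetaModel

from .barriers import BarrierSet
from .distances import DistanceMatrix

__all__ = [
    "MantelResult",
    "IbdModelFit",
    "ModelLadder",
    "mantel",
    "cluster_indicator_matrix",
    "him_ssm_protocol",
    "fit_beta_regression",
    "build_model_ladder",
]


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    scheme: str
    covariate: str | None = None
    strata: dict[str, str] | None = None
    interpretation: str | None = None


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("Mantel correlation undefined for a constant matrix")
    return float(np.corrcoef(x, y)[0, 1])


def _residual_matrix(m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Residuals of the off-diagonal entries of m regressed on those of c,
    reassembled into a symmetric zero-diagonal matrix."""
    n = m.shape[0]
    iu = np.triu_indices(n, 1)
    y, x = m[iu], c[iu]
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    res = y - X @ beta
    out = np.zeros_like(m, dtype=float)
    out[iu] = res
    out += out.T
    return out


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    scheme: str = "standard",
    permutations: int = 999,
    strata: dict[str, str] | None = None,
    covariate: DistanceMatrix | None = None,
    seed: int = 0,
    whole_stratum: bool = False,
) -> MantelResult:
    """Mantel test between two labelled distance matrices.

    schemes:
      * standard — permute entity labels of ``a``.
      * stratified — permutations restricted to label swaps within each
        stratum (``strata``: label -> stratum). ``whole_stratum=True``
        instead permutes entire equal-sized strata blocks.
      * partial — correlate the residuals of ``a`` and ``b`` after
        regressing each on ``covariate``; residual labels of ``a`` are
        permuted.

    One-tailed p = (1 + #{r_perm >= r_obs}) / (1 + permutations).
    """
    if sorted(a.labels) != sorted(b.labels):
        raise ValueError("matrices must share labels")
    b = b.reorder(a.labels)
    A, B = a.values, b.values
    cov_label = None
    if scheme == "partial":
        if covariate is None:
            raise ValueError("partial scheme requires a covariate matrix")
        C = covariate.reorder(a.labels).values
        cov_label = covariate.kind
        A = _residual_matrix(A, C)
        B = _residual_matrix(B, C)
    elif scheme == "stratified":
        if strata is None:
            raise ValueError("stratified scheme requires strata")
    elif scheme != "standard":
        raise ValueError(f"unknown scheme {scheme!r}")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")

    r_obs = _pearson(_offdiag(A), _offdiag(B))
    n = len(a.labels)
    rng = np.random.default_rng(seed)
    vb = _offdiag(B)
    iu = np.triu_indices(n, 1)

    if scheme == "stratified":
        groups = [
            np.array([i for i, l in enumerate(a.labels) if strata[l] == s])
            for s in dict.fromkeys(strata[l] for l in a.labels)
        ]

    count = 0
    for _ in range(permutations):
        if scheme == "stratified":
            perm = np.arange(n)
            if whole_stratum:
                sizes: dict[int, list] = {}
                for g in groups:
                    sizes.setdefault(len(g), []).append(g)
                for same in sizes.values():
                    order = rng.permutation(len(same))
                    for g, g2_i in zip(same, order):
                        perm[g] = same[g2_i]
            else:
                for g in groups:
                    perm[g] = g[rng.permutation(len(g))]
        else:
            perm = rng.permutation(n)
        r_perm = _pearson(A[np.ix_(perm, perm)][iu], vb)
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    return MantelResult(r_obs, float(p), permutations, scheme, cov_label, strata)


def cluster_indicator_matrix(
    labels: list[str], clusters: dict[str, str]
) -> DistanceMatrix:
    """Binary matrix: 1 iff two populations belong to different genetic clusters."""
    n = len(labels)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = float(clusters[labels[i]] != clusters[labels[j]])
    return DistanceMatrix(list(labels), v, "cluster-indicator")


def him_ssm_protocol(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    clusters: dict[str, str],
    permutations: int = 4999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """The four-test Mantel protocol separating hierarchical-island (HIM)
    from stepping-stone (SSM) structure.

    Tests: genetic~geographic standard; the same stratified within clusters;
    partial genetic~geographic with the cluster-indicator as covariate; and
    genetic~cluster-indicator partialling out geography. Interpretation tags
    attach the conventional decision rules (a significant stratified or
    partial-geography test indicates distance effects within/beyond clusters,
    i.e. SSM; a significant cluster effect net of geography indicates HIM).
    """
    ind = cluster_indicator_matrix(genetic.labels, clusters)
    single_cluster = len(set(clusters.values())) < 2
    rows = []
    t1 = mantel(genetic, geographic, "standard", permutations, seed=seed)
    t1.interpretation = "no discrimination (both models can produce this)"
    rows.append(("genetic", "geographic", "-", t1))
    t2 = mantel(genetic, geographic, "stratified", permutations, strata=clusters, seed=seed + 1)
    t2.interpretation = (
        "supports HIM (non-significant)" if t2.p > alpha else "supports SSM (significant within-cluster IBD)"
    )
    rows.append(("genetic", "geographic", "stratified: permuted within clusters", t2))
    if not single_cluster:
        t3 = mantel(genetic, geographic, "partial", permutations, covariate=ind, seed=seed + 2)
        t3.interpretation = (
            "supports SSM (significant, high r)" if t3.p <= alpha else "supports HIM (non-significant)"
        )
        rows.append(("genetic", "geographic", "partial: clusters as covariate", t3))
        t4 = mantel(genetic, ind, "partial", permutations, covariate=geographic, seed=seed + 3)
        t4.interpretation = (
            "supports HIM (significant cluster effect)" if t4.p <= alpha else "no cluster effect net of geography"
        )
        rows.append(("genetic", "clusters", "partial: geography as covariate", t4))
    return pd.DataFrame(
        [
            {
                "matrix_a": a_,
                "matrix_b": b_,
                "adjustment": adj,
                "r": t.r,
                "p": t.p,
                "interpretation": t.interpretation,
            }
            for a_, b_, adj, t in rows
        ]
    )


# ---------------------------------------------------------------------------
# Beta regression
# ---------------------------------------------------------------------------

@dataclass
class IbdModelFit:
    covariates: list[str]
    coefficients: pd.Series
    std_errors: pd.Series
    precision: float
    loglik: float
    aic: float
    pseudo_r2: float
    transform: dict = field(default_factory=dict)
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.coefficients) + 1  # + precision


def fit_beta_regression(y: np.ndarray, X: pd.DataFrame, maxiter: int = 500) -> IbdModelFit:
    """Beta regression with logit mean link and constant precision.

    Maximum likelihood via statsmodels' beta model, started from OLS on the
    link-transformed response with a method-of-moments precision estimate.
    pseudo-R2 is the squared Pearson correlation between the link-transformed
    response and the fitted linear predictor (Ferrari & Cribari-Neto).
    """
    y = np.asarray(y, float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("response must lie strictly inside (0, 1); transform first")
    Xd = pd.DataFrame(X).copy()
    if "const" not in Xd.columns:
        Xd.insert(0, "const", 1.0)
    if len(y) <= Xd.shape[1] + 1:
        raise ValueError("too few observations for the number of parameters")
    eta0 = logit(y)
    beta0, *_ = np.linalg.lstsq(Xd.values, eta0, rcond=None)
    mu0 = expit(Xd.values @ beta0)
    resid_var = max(np.var(y - mu0), 1e-8)
    phi0 = max(float(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0), 1.0)
    model = BetaModel(y, Xd)
    start = np.concatenate([beta0, [np.log(phi0)]])
    flags = []
    res = None
    for attempt, sp in enumerate([start, None]):
        try:
            res = model.fit(start_params=sp, maxiter=maxiter, disp=False)
        except Exception:
            continue
        if res.mle_retvals.get("converged", True):
            break
        flags.append(f"restart {attempt}: optimizer did not converge")
    if res is None:
        raise RuntimeError("beta regression failed to converge after restarts")
    params = pd.Series(np.asarray(res.params), index=list(Xd.columns) + ["precision(log)"])
    coef = params[:-1]
    bse = pd.Series(np.asarray(res.bse), index=params.index)[:-1]
    eta_hat = Xd.values @ coef.values
    pseudo_r2 = float(np.corrcoef(eta0, eta_hat)[0, 1] ** 2) if np.std(eta_hat) > 0 else 0.0
    k = len(coef) + 1
    return IbdModelFit(
        covariates=[c for c in Xd.columns if c != "const"],
        coefficients=coef,
        std_errors=bse,
        precision=float(np.exp(params.iloc[-1])),
        loglik=float(res.llf),
        aic=float(-2 * res.llf + 2 * k),
        pseudo_r2=pseudo_r2,
        converged=bool(res.mle_retvals.get("converged", True)),
        flags=flags,
    )


def rescale_to_unit(d: np.ndarray) -> tuple[np.ndarray, dict]:
    """Map distances into (0,1): min-max rescaling followed by the
    Smithson-Verkuilen compression y'' = (y'(n-1) + 0.5)/n."""
    d = np.asarray(d, float)
    lo, hi = d.min(), d.max()
    if hi <= lo:
        raise ValueError("constant response cannot be rescaled to (0,1)")
    y = (d - lo) / (hi - lo)
    n = len(d)
    y = (y * (n - 1) + 0.5) / n
    return y, {"min": float(lo), "max": float(hi), "compression_n": n}


@dataclass
class ModelLadder:
    fits: list[IbdModelFit]
    barrier_definition: str
    best_index: int
    transform: dict

    @property
    def best(self) -> IbdModelFit:
        return self.fits[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": " + ".join(["geographic"] + f.covariates[1:]) if f.covariates else "intercept",
                    "n_covariates": len(f.covariates),
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "pseudo_r2": f.pseudo_r2,
                    "best": i == self.best_index,
                }
                for i, f in enumerate(self.fits)
            ]
        )


def _straddle_columns(labels, clusters) -> dict[str, np.ndarray]:
    """One indicator per cluster: the pair straddles that cluster's boundary."""
    iu = np.triu_indices(len(labels), 1)
    cols = {}
    for c in dict.fromkeys(clusters[l] for l in labels):
        inc = np.array([clusters[l] == c for l in labels])
        m = (inc[:, None] != inc[None, :]).astype(float)
        cols[f"barrier_{c}"] = m[iu]
    return cols


def _barrier_columns(labels, barrier_set: BarrierSet) -> dict[str, np.ndarray]:
    """Cumulative indicators: pair separated by barriers 1..k."""
    iu = np.triu_indices(len(labels), 1)
    cols = {}
    for k in range(1, len(barrier_set.barriers) + 1):
        m = np.zeros((len(labels), len(labels)))
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                m[i, j] = m[j, i] = float(
                    barrier_set.separated(labels[i], labels[j], upto=k)
                )
        cols[f"barrier_1_to_{k}"] = m[iu]
    return cols


def build_model_ladder(
    nei: DistanceMatrix,
    geo: DistanceMatrix,
    barrier_def: str,
    components,
) -> ModelLadder:
    """Fit the ladder of beta-regression IBD models.

    The response is the vector of off-diagonal genetic distances mapped into
    (0,1) (shared across all fits); the base model uses geographic distance
    (rescaled by its maximum) alone, and each subsequent model adds one more
    barrier covariate. ``barrier_def``:

      * "structure-clusters": ``components`` is a population -> cluster map;
        one indicator per cluster boundary, added in cluster order.
      * "barrier-order": ``components`` is a BarrierSet; cumulative
        indicators for separation by barriers 1..k, added in barrier order.

    The best model is the one with minimal AIC. Covariate columns identical
    to one already present are skipped (they would be unidentifiable).
    """
    geo = geo.reorder(nei.labels)
    y, transform = rescale_to_unit(_offdiag(nei.values))
    g = _offdiag(geo.values)
    g = g / g.max() if g.max() > 0 else g
    base = pd.DataFrame({"geographic": g})
    if barrier_def == "structure-clusters":
        cols = _straddle_columns(nei.labels, components)
    elif barrier_def == "barrier-order":
        cols = _barrier_columns(nei.labels, components)
    else:
        raise ValueError(f"unknown barrier_def {barrier_def!r}")

    fits = [fit_beta_regression(y, base)]
    X = base
    for name, col in cols.items():
        if col.std() == 0:
            continue
        if any(np.array_equal(col, X[c].values) for c in X.columns):
            continue
        X = X.copy()
        X[name] = col
        flags = []
        if _is_separating(col, y):
            flags.append(f"{name} separates response extremes")
        fit = fit_beta_regression(y, X)
        fit.flags.extend(flags)
        fits.append(fit)
    best = int(np.argmin([f.aic for f in fits]))
    return ModelLadder(fits, barrier_def, best, transform)


def _is_separating(col: np.ndarray, y: np.ndarray) -> bool:
    on, off = y[col > 0.5], y[col <= 0.5]
    return len(on) > 0 and len(off) > 0 and (on.min() > off.max() or off.min() > on.max())
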