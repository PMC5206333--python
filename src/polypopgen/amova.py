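"""Analysis of molecular variance (AMOVA) on dominant (binary band) data.

Hierarchical partition of squared Euclidean distances between individual
band-presence vectors into among-cluster, among-population-within-cluster
and within-population components, with Phi-statistics and permutation
significance; pairwise Phi_ST used as FST and Slatkin gene-flow estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import DominantMatrix

__all__ = [
    "AmovaResult",
    "PairwiseFstResult",
    "amova_three_level",
    "amova_two_level",
    "pairwise_fst",
    "slatkin_nm",
    "squared_distances",
]


def percentages_from_components(components) -> np.ndarray:
    """Percentage of total variation per component (negatives truncated at 0)."""
    trunc = np.maximum(np.asarray(components, float), 0.0)
    total = trunc.sum()
    if total <= 0:
        raise ValueError("no positive variance component")
    return 100.0 * trunc / total


def squared_distances(dm: DominantMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distances between band vectors.

    Missing bands are pairwise-deleted and the sum rescaled by
    total-bands / compared-bands, so all individuals stay usable.
    """
    X = dm.values.astype(float)
    X[dm.missing] = np.nan
    n, B = X.shape
    D2 = np.zeros((n, n))
    valid = ~np.isnan(X)
    for i in range(n):
        diff = X[i] - X
        shared = valid[i] & valid
        diff[~shared] = 0.0
        cnt = shared.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            D2[i] = np.where(cnt > 0, (diff**2).sum(axis=1) * (B / cnt), np.nan)
    np.fill_diagonal(D2, 0.0)
    return D2


def _ss_within_groups(D2: np.ndarray, labels: np.ndarray) -> float:
    """Sum over groups of (1/n_g) * sum of squared distances within the group."""
    ss = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        if len(idx) < 2:
            continue
        sub = D2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


@dataclass
class AmovaResult:
    table: pd.DataFrame  # rows: among_clusters, among_pops_within, within_pops, total
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_values: dict[str, float]
    permutations: int
    flags: list[str]

    @property
    def percentages(self) -> pd.Series:
        return self.table["percentage"]


def _three_level_components(D2, pop_idx, clu_of_pop):
    """df, SS and variance components of the nested three-level design."""
    N = len(pop_idx)
    pops = np.unique(pop_idx)
    clu_idx = np.array([clu_of_pop[p] for p in pop_idx])
    clusters = np.unique(clu_idx)
    P, G = len(pops), len(clusters)

    ss_total = D2[np.triu_indices(N, 1)].sum() / N
    ss_wp = _ss_within_groups(D2, pop_idx)
    ss_wc = _ss_within_groups(D2, clu_idx)
    ss_ap = ss_wc - ss_wp
    ss_ac = ss_total - ss_wc

    df_ac, df_ap, df_wp = G - 1, P - G, N - P
    n_p = np.array([np.sum(pop_idx == p) for p in pops], float)
    N_c = np.array([np.sum(clu_idx == c) for c in clusters], float)
    sum_np2_by_c = np.array([
        sum(np.sum(pop_idx == p) ** 2 for p in pops if clu_of_pop[p] == c)
        for c in clusters
    ], float)

    n1 = (N - (sum_np2_by_c / N_c).sum()) / df_ap if df_ap > 0 else np.nan
    n2 = ((sum_np2_by_c / N_c).sum() - (n_p**2).sum() / N) / df_ac
    n3 = (N - (N_c**2).sum() / N) / df_ac

    ms_wp = ss_wp / df_wp
    sigma_w = ms_wp
    sigma_b = (ss_ap / df_ap - sigma_w) / n1 if df_ap > 0 else 0.0
    sigma_a = (ss_ac / df_ac - sigma_w - n2 * sigma_b) / n3
    return (df_ac, df_ap, df_wp), (ss_ac, ss_ap, ss_wp, ss_total), (sigma_a, sigma_b, sigma_w)


def amova_three_level(
    dm: DominantMatrix,
    populations: dict[str, str] | None = None,
    clusters: dict[str, str] | None = None,
    permutations: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA: clusters / populations within clusters / individuals.

    ``clusters`` maps population label -> cluster label. Variance components
    are solved from expected mean squares with unbalanced-design
    coefficients; Phi statistics follow. Significance uses the three standard
    permutation schemes: individuals among populations anywhere (Phi_ST),
    individuals among populations within clusters (Phi_SC), and whole
    populations among clusters (Phi_CT).
    """
    pop_of = populations or dm.population_of
    if clusters is None:
        raise ValueError("clusters mapping (population -> cluster) is required")
    pop_labels = np.array([pop_of[i] for i in dm.individuals])
    pops = list(dict.fromkeys(pop_labels))
    missing_cluster = [p for p in pops if p not in clusters]
    if missing_cluster:
        raise ValueError(f"populations without cluster: {missing_cluster}")
    flags = []
    clu_count: dict[str, int] = {}
    for p in pops:
        clu_count[clusters[p]] = clu_count.get(clusters[p], 0) + 1
    for c, k in clu_count.items():
        if k == 1:
            flags.append(f"cluster {c!r} holds a single population; Phi_SC partially confounded")
    if len(clu_count) < 2:
        raise ValueError("need at least two clusters")

    D2 = squared_distances(dm)
    pop_index = {p: k for k, p in enumerate(pops)}
    pop_idx = np.array([pop_index[p] for p in pop_labels])
    clu_of_pop = {pop_index[p]: clusters[p] for p in pops}

    dfs, sss, comps = _three_level_components(D2, pop_idx, clu_of_pop)
    sigma_a, sigma_b, sigma_w = comps
    # truncated components for percentage reporting (signed retained in table)
    pct = percentages_from_components(comps)
    total_var = sigma_a + sigma_b + sigma_w
    phi_ct = sigma_a / total_var
    phi_sc = sigma_b / (sigma_b + sigma_w)
    phi_st = (sigma_a + sigma_b) / total_var

    rng = np.random.default_rng(seed)
    p_st = p_sc = p_ct = np.nan
    if permutations > 0:
        null_st = np.empty(permutations)
        null_sc = np.empty(permutations)
        null_ct = np.empty(permutations)
        clu_idx = np.array([clu_of_pop[p] for p in pop_idx])
        for b in range(permutations):
            # Phi_ST: individuals among populations, anywhere
            perm = rng.permutation(pop_idx)
            _, _, (sa, sb, sw) = _three_level_components(D2, perm, clu_of_pop)
            null_st[b] = (sa + sb) / (sa + sb + sw)
            # Phi_SC: individuals among populations within clusters
            perm = pop_idx.copy()
            for c in np.unique(clu_idx):
                rows = np.where(clu_idx == c)[0]
                perm[rows] = perm[rng.permutation(rows)]
            _, _, (sa, sb, sw) = _three_level_components(D2, perm, clu_of_pop)
            null_sc[b] = sb / (sb + sw)
            # Phi_CT: whole populations among clusters
            shuffled = rng.permutation([clu_of_pop[pop_index[p]] for p in pops])
            cmap = {pop_index[p]: shuffled[k] for k, p in enumerate(pops)}
            _, _, (sa, sb, sw) = _three_level_components(D2, pop_idx, cmap)
            null_ct[b] = sa / (sa + sb + sw)

        def pval(obs, null):
            return float((1 + np.sum(null >= obs - 1e-12)) / (1 + len(null)))

        p_st, p_sc, p_ct = pval(phi_st, null_st), pval(phi_sc, null_sc), pval(phi_ct, null_ct)

    table = pd.DataFrame(
        {
            "df": [dfs[0], dfs[1], dfs[2], sum(dfs)],
            "SS": [sss[0], sss[1], sss[2], sss[3]],
            "variance": [sigma_a, sigma_b, sigma_w, total_var],
            "percentage": [pct[0], pct[1], pct[2], 100.0],
        },
        index=["among_clusters", "among_pops_within_clusters", "within_pops", "total"],
    )
    return AmovaResult(
        table=table,
        phi_ct=float(phi_ct),
        phi_sc=float(phi_sc),
        phi_st=float(phi_st),
        p_values={"phi_ct": p_ct, "phi_sc": p_sc, "phi_st": p_st},
        permutations=permutations,
        flags=flags,
    )


def _two_level_components(D2: np.ndarray, pop_idx: np.ndarray):
    N = len(pop_idx)
    pops, counts = np.unique(pop_idx, return_counts=True)
    P = len(pops)
    ss_total = D2[np.triu_indices(N, 1)].sum() / N
    ss_wp = _ss_within_groups(D2, pop_idx)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, N - P
    n_c = (N - (counts.astype(float) ** 2).sum() / N) / df_ap
    sigma_w = ss_wp / df_wp
    sigma_a = (ss_ap / df_ap - sigma_w) / n_c
    return (df_ap, df_wp), (ss_ap, ss_wp, ss_total), (sigma_a, sigma_w)


def amova_two_level(
    dm: DominantMatrix,
    populations: dict[str, str] | None = None,
    permutations: int = 0,
    seed: int = 0,
):
    """Two-level AMOVA (among / within populations); Phi_ST is the global FST."""
    pop_of = populations or dm.population_of
    pop_labels = np.array([pop_of[i] for i in dm.individuals])
    pops = list(dict.fromkeys(pop_labels))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    D2 = squared_distances(dm)
    pop_index = {p: k for k, p in enumerate(pops)}
    pop_idx = np.array([pop_index[p] for p in pop_labels])
    dfs, sss, (sigma_a, sigma_w) = _two_level_components(D2, pop_idx)
    phi_st = sigma_a / (sigma_a + sigma_w)
    p = np.nan
    if permutations > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(permutations)
        for b in range(permutations):
            _, _, (sa, sw) = _two_level_components(D2, rng.permutation(pop_idx))
            null[b] = sa / (sa + sw)
        p = float((1 + np.sum(null >= phi_st - 1e-12)) / (1 + permutations))
    return {
        "df": dfs,
        "SS": sss,
        "variance": (sigma_a, sigma_w),
        "phi_st": float(phi_st),
        "p_value": p,
    }


@dataclass
class PairwiseFstResult:
    fst: pd.DataFrame
    nm: pd.DataFrame
    p_values: pd.DataFrame
    global_fst: float
    global_p: float
    skipped: list[tuple[str, str]]

    def combined_table(self) -> pd.DataFrame:
        """FST above the diagonal, Nm below (conventional report layout)."""
        out = self.fst.copy()
        pops = list(out.index)
        for i, a in enumerate(pops):
            for j, b in enumerate(pops):
                if i > j:
                    out.iloc[i, j] = self.nm.iloc[i, j]
                elif i == j:
                    out.iloc[i, j] = np.nan
        return out


def slatkin_nm(fst: float, form: str = "diploid", cap: float = 1e6) -> float:
    """Slatkin's gene-flow estimate from FST.

    diploid form Nm = (1/FST - 1)/4 (default); haploid form (1/FST - 1)/2.
    FST = 0 gives the cap; FST = 1 gives 0.
    """
    k = 4.0 if form == "diploid" else 2.0
    if form not in ("diploid", "haploid"):
        raise ValueError(f"unknown form {form!r}")
    if fst <= 0:
        return cap
    if fst >= 1:
        return 0.0
    return (1.0 / fst - 1.0) / k


def pairwise_fst(
    dm: DominantMatrix,
    populations: dict[str, str] | None = None,
    permutations: int = 199,
    seed: int = 0,
    nm_form: str = "diploid",
) -> PairwiseFstResult:
    """Pairwise Phi_ST (as FST, truncated at 0), Slatkin Nm and p-values.

    Each pair is scored by a two-level AMOVA restricted to the two
    populations; the global FST comes from the all-population two-level
    AMOVA. Populations of one individual are skipped with a warning.
    """
    pop_of = populations or dm.population_of
    pop_labels = np.array([pop_of[i] for i in dm.individuals])
    pops = list(dict.fromkeys(pop_labels))
    D2 = squared_distances(dm)
    fst = pd.DataFrame(np.nan, index=pops, columns=pops)
    nm = pd.DataFrame(np.nan, index=pops, columns=pops)
    pv = pd.DataFrame(np.nan, index=pops, columns=pops)
    skipped = []
    rng = np.random.default_rng(seed)
    for a_i in range(len(pops)):
        fst.iloc[a_i, a_i] = 0.0
        for b_i in range(a_i + 1, len(pops)):
            a, b = pops[a_i], pops[b_i]
            rows = np.where((pop_labels == a) | (pop_labels == b))[0]
            if min(np.sum(pop_labels == a), np.sum(pop_labels == b)) < 2:
                skipped.append((a, b))
                continue
            sub = D2[np.ix_(rows, rows)]
            idx = (pop_labels[rows] == b).astype(int)
            _, _, (sa, sw) = _two_level_components(sub, idx)
            f = max(sa / (sa + sw), 0.0)
            fst.loc[a, b] = fst.loc[b, a] = f
            nm.loc[a, b] = nm.loc[b, a] = slatkin_nm(f, nm_form)
            if permutations > 0:
                null = np.empty(permutations)
                for k in range(permutations):
                    _, _, (na, nw) = _two_level_components(sub, rng.permutation(idx))
                    null[k] = na / (na + nw)
                pv.loc[a, b] = pv.loc[b, a] = float(
                    (1 + np.sum(null >= f - 1e-12)) / (1 + permutations)
                )
    glob = amova_two_level(dm, pop_of, permutations=permutations, seed=seed + 1)
    return PairwiseFstResult(
        fst=fst,
        nm=nm,
        p_values=pv,
        global_fst=max(glob["phi_st"], 0.0),
        global_p=glob["p_value"],
        skipped=skipped,
    )
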