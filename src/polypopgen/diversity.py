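"""Genetic-diversity statistics for tetraploid populations.

Covers allele frequencies (with explicit dosage-ambiguity policies), Nei's
unbiased gene diversity He and total diversity HT, rarefied allelic richness,
private alleles, and inbreeding coefficients (individual Fi and multilocus
FIS) with permutation significance. Negative FIS indicates heterozygote
excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import PLOIDY, GenotypeMatrix

__all__ = [
    "AlleleFrequencyTable",
    "DiversityReport",
    "allele_frequencies",
    "gene_diversity",
    "allelic_richness",
    "total_gene_diversity",
    "private_alleles",
    "inbreeding_coefficients",
    "diversity_report",
]


@dataclass
class AlleleFrequencyTable:
    """Allele frequencies per (population, locus).

    freqs[(pop, locus)] maps allele size -> frequency; copies[(pop, locus)]
    is the number of gene copies behind the estimate (4 per usable cell).
    counts holds the (possibly fractional, under equal-split) copy counts.
    """

    populations: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]
    copies: dict[tuple[str, str], float]
    counts: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    empty_cells: list[tuple[str, str]] = field(default_factory=list)

    def alleles_at(self, locus: str) -> list[int]:
        out: set[int] = set()
        for p in self.populations:
            out.update(self.freqs.get((p, locus), {}))
        return sorted(out)

    def pooled_counts(self, locus: str) -> dict[int, float]:
        out: dict[int, float] = {}
        for p in self.populations:
            for a, c in self.counts.get((p, locus), {}).items():
                out[a] = out.get(a, 0.0) + c
        return out


def allele_frequencies(gm: GenotypeMatrix, dosage_policy: str = "equal-split") -> AlleleFrequencyTable:
    """Estimate per-population allele frequencies.

    dosage_policy:
      * "equal-split" (default): an ambiguous cell with k distinct alleles
        contributes 4/k gene copies to each, so every non-missing cell weighs
        four copies.
      * "known-only": dosage-ambiguous cells are excluded entirely.
    """
    if dosage_policy not in ("equal-split", "known-only"):
        raise ValueError(f"unknown dosage_policy {dosage_policy!r}")
    pops = gm.populations
    loci = [l.name for l in gm.loci]
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    copies: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], dict[int, float]] = {}
    empties: list[tuple[str, str]] = []
    for l, locus in enumerate(gm.loci):
        for pop in pops:
            acc: dict[int, float] = {}
            total = 0.0
            for i, ind in enumerate(gm.individuals):
                if gm.population_of[ind] != pop:
                    continue
                g = gm.cells[i][l]
                if g.missing:
                    continue
                if dosage_policy == "known-only" and not g.dosage_known:
                    continue
                for a, c in g.copy_counts().items():
                    acc[a] = acc.get(a, 0.0) + c
                total += PLOIDY
            key = (pop, locus.name)
            counts[key] = acc
            copies[key] = total
            if total == 0:
                freqs[key] = {}
                empties.append(key)
            else:
                freqs[key] = {a: c / total for a, c in acc.items()}
    return AlleleFrequencyTable(pops, loci, freqs, copies, counts, empties)


def gene_diversity(freqs: dict[int, float], n_copies: float) -> float:
    """Nei's (1978) unbiased gene diversity for one population x locus.

    He = (n/(n-1)) (1 - sum p^2), n = gene copies. Returns nan when fewer
    than two copies are available.
    """
    if n_copies < 2:
        return float("nan")
    ss = sum(p * p for p in freqs.values())
    return float(n_copies / (n_copies - 1.0) * (1.0 - ss))


def _expected_alleles(counts: np.ndarray, g: int) -> float:
    """E[# distinct alleles in a sample of g copies], hypergeometric rarefaction.

    counts may be fractional (equal-split); the binomial-coefficient ratio
    C(N-Na, g)/C(N, g) is evaluated as a product so it extends continuously.
    """
    N = counts.sum()
    if g > N + 1e-9:
        raise ValueError(f"rarefaction size g={g} exceeds available copies {N}")
    total = 0.0
    for Na in counts:
        ratio = 1.0
        for i in range(g):
            ratio *= max(N - Na - i, 0.0) / (N - i)
        total += 1.0 - ratio
    return total


def allelic_richness(table: AlleleFrequencyTable, g: int | None = None) -> pd.DataFrame:
    """Rarefied allelic richness per population (and multilocus mean).

    g is the standard sample size in gene copies; default is the smallest
    per-(population, locus) copy count, i.e. rarefaction to the smallest
    sample. Returns a populations x loci frame plus a "multilocus" column.
    """
    nonzero = [c for c in table.copies.values() if c > 0]
    if g is None:
        g = int(min(nonzero))
    if g < 2:
        raise ValueError("rarefaction size must be >= 2")
    rows = {}
    for pop in table.populations:
        vals = []
        for loc in table.loci:
            cnt = table.counts.get((pop, loc), {})
            if not cnt:
                vals.append(np.nan)
                continue
            vals.append(_expected_alleles(np.array(list(cnt.values()), float), g))
        rows[pop] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=table.loci)
    df["multilocus"] = df[table.loci].mean(axis=1)
    df.attrs["g"] = g
    return df


def total_gene_diversity(table: AlleleFrequencyTable) -> float:
    """Total gene diversity HT over all populations (multilocus mean).

    Per locus, allele frequencies are averaged over populations (unweighted)
    and the Nei small-sample correction n/(n-1) is applied with n the total
    gene copies across populations.
    """
    if len(table.populations) < 2:
        raise ValueError("HT requires at least two populations")
    per_locus = []
    for loc in table.loci:
        pops = [p for p in table.populations if table.freqs.get((p, loc))]
        if not pops:
            continue
        alleles = table.alleles_at(loc)
        pbar = np.array([
            np.mean([table.freqs[(p, loc)].get(a, 0.0) for p in pops]) for a in alleles
        ])
        n = sum(table.copies[(p, loc)] for p in pops)
        per_locus.append(n / (n - 1.0) * (1.0 - float(pbar @ pbar)))
    return float(np.mean(per_locus))


def private_alleles(table: AlleleFrequencyTable, denominator: str = "global") -> pd.Series:
    """Percentage of private alleles per population, plus the total.

    An allele is private when it segregates in exactly one population. With
    denominator="global" (default) the percentage divides by the total number
    of distinct alleles across all populations and loci, so the
    per-population values sum to the total row; denominator="own" instead
    divides each population's private count by its own allele count (the
    total row is then the mean).
    """
    if len(table.populations) < 2:
        raise ValueError("private alleles require at least two populations")
    if denominator not in ("global", "own"):
        raise ValueError(f"unknown denominator {denominator!r}")
    total_alleles = 0
    own: dict[str, int] = {p: 0 for p in table.populations}
    private: dict[str, int] = {p: 0 for p in table.populations}
    for loc in table.loci:
        for a in table.alleles_at(loc):
            holders = [
                p for p in table.populations if table.freqs.get((p, loc), {}).get(a, 0.0) > 0
            ]
            total_alleles += 1
            for p in holders:
                own[p] += 1
            if len(holders) == 1:
                private[holders[0]] += 1
    if denominator == "global":
        pct = {p: 100.0 * k / total_alleles for p, k in private.items()}
        out = pd.Series(pct)
        out["total"] = out.sum()
    else:
        pct = {p: 100.0 * k / own[p] if own[p] else 0.0 for p, k in private.items()}
        out = pd.Series(pct)
        out["total"] = out.drop("total", errors="ignore").mean()
    out.attrs["total_alleles"] = total_alleles
    return out


# ---------------------------------------------------------------------------
# Inbreeding coefficients
# ---------------------------------------------------------------------------

def _copy_matrix(gm: GenotypeMatrix, rng: np.random.Generator) -> np.ndarray:
    """Integer gene-copy matrix (individuals x loci x 4 allele sizes).

    Dosage-ambiguous cells are resolved by drawing one completion uniformly
    at random (seeded); missing cells are coded -1.
    """
    n, L = len(gm.individuals), len(gm.loci)
    arr = np.full((n, L, PLOIDY), -1, dtype=np.int32)
    for i in range(n):
        for l in range(L):
            g = gm.cells[i][l]
            if g.missing:
                continue
            comps = g.completions()
            arr[i, l] = comps[rng.integers(len(comps))] if len(comps) > 1 else comps[0]
    return arr


def _fis_components(arr: np.ndarray, pop_idx: np.ndarray, n_pops: int):
    """Per-locus sums of (Q_ind - Q_pop) and (1 - Q_pop) plus per-individual Fi parts.

    Q_ind is the identity-in-state over the six within-individual copy pairs;
    Q_pop the identity over between-individual copy pairs within the same
    population. Monomorphic population x locus combinations contribute
    nothing (their denominator is zero).
    """
    n, L, P = arr.shape
    num_ml = 0.0
    den_ml = 0.0
    fi_num = np.zeros(n)
    fi_den = np.zeros(n)
    for l in range(L):
        for p in range(n_pops):
            rows = np.where(pop_idx == p)[0]
            sub = arr[rows, l, :]
            ok = sub[:, 0] >= 0
            sub = sub[ok]
            rows = rows[ok]
            if len(sub) < 2:
                continue
            # within-individual identity
            eq = (sub[:, :, None] == sub[:, None, :])
            iu = np.triu_indices(P, 1)
            q_ind = eq[:, iu[0], iu[1]].mean(axis=1)
            # between-individual identity from copy counts
            alleles, inv = np.unique(sub, return_inverse=True)
            inv = inv.reshape(sub.shape)
            cnt = np.zeros((len(sub), len(alleles)))
            for c in range(P):
                np.add.at(cnt, (np.arange(len(sub)), inv[:, c]), 1)
            tot = cnt.sum(axis=0)
            m = len(sub)
            # sum over pairs i!=j of matches, divided by pairs * P^2
            cross = tot[None, :] - cnt
            q_between = (cnt * cross).sum() / (m * (m - 1) * P * P)
            if q_between >= 1.0 - 1e-12:
                continue  # monomorphic: denominator zero
            num_ml += float(np.sum(q_ind - q_between))
            den_ml += m * (1.0 - q_between)
            fi_num[rows] += q_ind - q_between
            fi_den[rows] += 1.0 - q_between
    return num_ml, den_ml, fi_num, fi_den


@dataclass
class InbreedingResult:
    fi_individual: pd.Series
    fi_population: pd.Series
    fi_pvalues: pd.Series
    fis_multilocus: float
    fis_pvalue: float
    permutations: int
    seed: int


def inbreeding_coefficients(
    gm: GenotypeMatrix, permutations: int = 999, seed: int = 0
) -> InbreedingResult:
    """Individual (Fi) and multilocus (FIS) inbreeding coefficients.

    Fi = (Q_ind - Q_pop) / (1 - Q_pop), the kinship between homologous gene
    copies within an individual relative to its population; FIS aggregates
    numerators and denominators over loci and individuals. Significance is
    assessed by permuting gene copies among individuals within each
    population x locus (two-sided p-values).
    """
    rng = np.random.default_rng(seed)
    arr = _copy_matrix(gm, rng)
    pops = gm.populations
    pop_of = {p: k for k, p in enumerate(pops)}
    pop_idx = np.array([pop_of[gm.population_of[i]] for i in gm.individuals])

    num, den, fi_num, fi_den = _fis_components(arr, pop_idx, len(pops))
    fis = num / den if den > 0 else float("nan")
    with np.errstate(invalid="ignore"):
        fi_ind = np.where(fi_den > 0, fi_num / fi_den, np.nan)
    fi_series = pd.Series(fi_ind, index=gm.individuals)
    fi_pop_obs = {
        p: float(np.nanmean(fi_ind[pop_idx == pop_of[p]])) for p in pops
    }

    # permutation null: shuffle gene copies among individuals within pop x locus
    n, L, P = arr.shape
    fis_null = np.empty(permutations)
    fi_pop_null = np.empty((permutations, len(pops)))
    for b in range(permutations):
        perm = arr.copy()
        for l in range(L):
            for p in range(len(pops)):
                rows = np.where(pop_idx == p)[0]
                rows = rows[perm[rows, l, 0] >= 0]
                if len(rows) < 2:
                    continue
                pool = perm[rows, l, :].ravel()
                rng.shuffle(pool)
                perm[rows, l, :] = pool.reshape(len(rows), P)
        pn, pdn, pfin, pfid = _fis_components(perm, pop_idx, len(pops))
        fis_null[b] = pn / pdn if pdn > 0 else np.nan
        with np.errstate(invalid="ignore"):
            pfi = np.where(pfid > 0, pfin / pfid, np.nan)
        for k in range(len(pops)):
            fi_pop_null[b, k] = np.nanmean(pfi[pop_idx == k])

    def two_sided(obs: float, null: np.ndarray) -> float:
        null = null[~np.isnan(null)]
        if len(null) == 0 or np.isnan(obs):
            return float("nan")
        lo = (1 + np.sum(null <= obs)) / (1 + len(null))
        hi = (1 + np.sum(null >= obs)) / (1 + len(null))
        return float(min(1.0, 2 * min(lo, hi)))

    fis_p = two_sided(fis, fis_null)
    fi_p = {p: two_sided(fi_pop_obs[p], fi_pop_null[:, pop_of[p]]) for p in pops}
    return InbreedingResult(
        fi_series,
        pd.Series(fi_pop_obs),
        pd.Series(fi_p),
        float(fis),
        fis_p,
        permutations,
        seed,
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class DiversityReport:
    per_population: pd.DataFrame  # N, NA, AR, He, Fi, Fi_p, Pa
    ht: float
    fis_multilocus: float
    fis_pvalue: float
    na_total: float
    ar_total: float
    pa_total: float
    rarefaction_g: int

    def to_frame(self) -> pd.DataFrame:
        df = self.per_population.copy()
        total = {
            "N": df["N"].sum(),
            "NA": self.na_total,
            "AR": self.ar_total,
            "He": self.ht,
            "Fi": self.fis_multilocus,
            "Fi_p": self.fis_pvalue,
            "Pa": self.pa_total,
        }
        df.loc["Total"] = pd.Series(total)
        return df


def diversity_report(
    gm: GenotypeMatrix,
    dosage_policy: str = "equal-split",
    rarefaction_g: int | None = None,
    permutations: int = 999,
    seed: int = 0,
) -> DiversityReport:
    """Per-population diversity table plus totals (mirrors a standard SSR report)."""
    table = allele_frequencies(gm, dosage_policy)
    sizes = gm.population_sizes()
    ar = allelic_richness(table, rarefaction_g)
    inb = inbreeding_coefficients(gm, permutations=permutations, seed=seed)
    pa = private_alleles(table)

    rows = {}
    for pop in table.populations:
        na = np.mean([
            len(table.freqs.get((pop, loc), {})) for loc in table.loci
        ])
        he = np.nanmean([
            gene_diversity(table.freqs[(pop, loc)], table.copies[(pop, loc)])
            for loc in table.loci
            if table.freqs.get((pop, loc))
        ])
        rows[pop] = {
            "N": sizes[pop],
            "NA": float(na),
            "AR": float(ar.loc[pop, "multilocus"]),
            "He": float(he),
            "Fi": float(inb.fi_population[pop]),
            "Fi_p": float(inb.fi_pvalues[pop]),
            "Pa": float(pa[pop]),
        }
    per_pop = pd.DataFrame.from_dict(rows, orient="index")
    # totals: NA over pooled data, AR as mean of per-pop multilocus at pooled g
    na_total = np.mean([len(table.alleles_at(loc)) for loc in table.loci])
    pooled_counts = {
        loc: np.array(list(table.pooled_counts(loc).values()), float) for loc in table.loci
    }
    g = ar.attrs["g"]
    ar_total = float(np.mean([
        _expected_alleles(c, g) for c in pooled_counts.values() if c.size
    ]))
    return DiversityReport(
        per_population=per_pop,
        ht=total_gene_diversity(table),
        fis_multilocus=inb.fis_multilocus,
        fis_pvalue=inb.fis_pvalue,
        na_total=float(na_total),
        ar_total=ar_total,
        pa_total=float(pa["total"]),
        rarefaction_g=g,
    )
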