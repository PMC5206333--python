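"""Distance matrices: Bruvo (inter-individual), Nei (inter-population, from
dominant band data), and geographic great-circle distances.

The Bruvo distance compares microsatellite genotypes through repeat-count
differences, d = 1 - 2^-|x| per allele pair, minimised over bijective
assignments of the four gene copies; dosage-ambiguous genotypes are averaged
over all dosage completions (genome-addition behaviour).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations as _perms

import numpy as np
import pandas as pd

from .genotypes import PLOIDY, DominantMatrix, Genotype, GenotypeMatrix, Locus

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "bruvo_pair",
    "bruvo_matrix",
    "nei_distance",
    "geographic_matrix",
]

EARTH_RADIUS_M = 6_371_000.0
_ASSIGNMENTS = np.array(list(_perms(range(PLOIDY))))  # 24 x 4


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"
    capped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), 1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind, self.capped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(l) for l in df.index], df.values, kind)

    def to_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-style export for interchange."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{lab[:10]:<10s} {row}\n".rstrip() + "\n")


# ---------------------------------------------------------------------------
# Bruvo distance
# ---------------------------------------------------------------------------

def _bruvo_complete(r1: tuple, r2: tuple) -> float:
    """Bruvo distance between two dosage-complete repeat-count 4-tuples."""
    a = np.asarray(r1, float)
    b = np.asarray(r2, float)
    d = 1.0 - 2.0 ** (-np.abs(a[:, None] - b[None, :]))  # 4 x 4
    # min over the 24 bijective assignments of the mean per-allele distance
    return float(d[np.arange(PLOIDY), _ASSIGNMENTS].mean(axis=1).min())


@lru_cache(maxsize=200_000)
def _bruvo_cached(c1: tuple, c2: tuple) -> float:
    """Mean over dosage completions of the optimal-assignment distance.

    c1/c2 are tuples of completions (each a repeat-count 4-tuple).
    """
    total = 0.0
    for x in c1:
        for y in c2:
            total += _bruvo_complete(x, y)
    return total / (len(c1) * len(c2))


def _completion_key(g: Genotype, locus: Locus) -> tuple:
    return tuple(
        tuple(locus.repeat_count(a) for a in comp) for comp in g.completions()
    )


def bruvo_pair(g1: Genotype, g2: Genotype, motif_length: int, size_anchor: int = 0) -> float:
    """Bruvo distance between two tetraploid genotypes at one locus.

    Allele sizes are converted to repeat counts (size differences divided by
    motif length); each dosage-ambiguous genotype is expanded to all
    completions to four copies and the mean over completion pairs of the
    assignment-minimal distance is returned. Result lies in [0, 1].
    """
    if g1.missing or g2.missing:
        raise ValueError("bruvo_pair requires non-missing genotypes")
    lo = min(g1.distinct + g2.distinct)
    locus = Locus("_", motif_length, (min(lo, size_anchor or lo), max(g1.distinct + g2.distinct) + 1))
    return _bruvo_cached(_completion_key(g1, locus), _completion_key(g2, locus))


def bruvo_matrix(gm: GenotypeMatrix, allow_missing: bool = False) -> DistanceMatrix:
    """Inter-individual multilocus Bruvo distance matrix.

    The multilocus distance is the mean of per-locus distances over loci
    scored in both individuals. A pair sharing no scored locus is an error
    unless ``allow_missing`` (then the entry is nan).
    """
    n = len(gm.individuals)
    if n < 2:
        raise ValueError("need at least two individuals")
    L = len(gm.loci)
    keys: list[list[tuple | None]] = [[None] * L for _ in range(n)]
    for l, locus in enumerate(gm.loci):
        for i in range(n):
            g = gm.cells[i][l]
            if not g.missing:
                keys[i][l] = _completion_key(g, locus)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot, cnt = 0.0, 0
            for l in range(L):
                ki, kj = keys[i][l], keys[j][l]
                if ki is None or kj is None:
                    continue
                tot += _bruvo_cached(ki, kj)
                cnt += 1
            if cnt == 0:
                if not allow_missing:
                    raise ValueError(
                        f"individuals {gm.individuals[i]} and {gm.individuals[j]} share no scored locus"
                    )
                values[i, j] = values[j, i] = np.nan
            else:
                values[i, j] = values[j, i] = tot / cnt
    return DistanceMatrix(list(gm.individuals), values, "bruvo")


# ---------------------------------------------------------------------------
# Nei distance from dominant data
# ---------------------------------------------------------------------------

def _band_frequencies(dm: DominantMatrix, populations: list[str]) -> np.ndarray:
    """Band presence frequency per population (pops x bands), nan where unscored."""
    pops_of = np.array([dm.population_of[i] for i in dm.individuals])
    out = np.empty((len(populations), len(dm.bands)))
    for k, p in enumerate(populations):
        rows = pops_of == p
        vals = np.where(dm.missing[rows], np.nan, dm.values[rows].astype(float))
        with np.errstate(invalid="ignore"):
            out[k] = np.nanmean(vals, axis=0)
    return out


def nei_distance(
    dm: DominantMatrix,
    grouping: dict[str, str] | None = None,
    unbiased: bool = False,
    cap: float = 10.0,
) -> DistanceMatrix:
    """Nei's standard genetic distance between populations from band frequencies.

    Each band is treated as a biallelic locus with presence frequency p.
    D = -ln(J12 / sqrt(J1 J2)) with J12 = mean over bands of p1 p2 + (1-p1)(1-p2)
    and J1, J2 the within-population analogues. ``unbiased`` applies Nei's
    (1978) small-sample correction to the within-population J terms.
    Infinite distances (J12 = 0) are capped at ``cap`` and flagged.
    """
    pop_of = grouping or dm.population_of
    dm = DominantMatrix(dm.individuals, dm.bands, dm.values, dm.missing, dict(pop_of))
    populations = list(dict.fromkeys(pop_of[i] for i in dm.individuals))
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    freq = _band_frequencies(dm, populations)
    sizes = {p: sum(1 for i in dm.individuals if pop_of[i] == p) for p in populations}
    n = len(populations)
    values = np.zeros((n, n))
    capped = []
    for a in range(n):
        for b in range(a + 1, n):
            ok = ~np.isnan(freq[a]) & ~np.isnan(freq[b])
            p1, p2 = freq[a, ok], freq[b, ok]
            j12 = float(np.mean(p1 * p2 + (1 - p1) * (1 - p2)))
            j1 = float(np.mean(p1 * p1 + (1 - p1) * (1 - p1)))
            j2 = float(np.mean(p2 * p2 + (1 - p2) * (1 - p2)))
            if unbiased:
                # correction on within-pop homozygosity, 2n gene copies per band
                for jj, pop in ((0, populations[a]), (1, populations[b])):
                    m = 2 * sizes[pop]
                    if jj == 0:
                        j1 = max((m * j1 - 1.0) / (m - 1.0), 1e-12)
                    else:
                        j2 = max((m * j2 - 1.0) / (m - 1.0), 1e-12)
            if j12 <= 0:
                d = cap
                capped.append((populations[a], populations[b]))
                log.warning(
                    "Nei distance %s-%s infinite (J12=0); capped at %.1f",
                    populations[a], populations[b], cap,
                )
            else:
                d = max(-np.log(j12 / np.sqrt(j1 * j2)), 0.0)
                d = min(d, cap)
            values[a, b] = values[b, a] = d
    return DistanceMatrix(populations, values, "nei", capped)


# ---------------------------------------------------------------------------
# Geographic distances
# ---------------------------------------------------------------------------

def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres (Earth radius 6 371 000 m)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(min(h, 1.0))))


def geographic_matrix(coords: dict[str, tuple[float, float]], labels: list[str] | None = None) -> DistanceMatrix:
    """Great-circle distance matrix (metres) between population coordinates."""
    labels = list(labels) if labels is not None else list(coords)
    missing = [p for p in labels if p not in coords]
    if missing:
        raise ValueError(f"populations without coordinates: {missing}")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_m(*coords[labels[i]], *coords[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, "geographic")
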