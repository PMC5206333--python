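"""Synthetic tetraploid SSR data with known truth.

Two generators emulate the structure of an Azorean-archipelago style survey
(nine populations of 6-21 tetraploid individuals on four islands, eight
microsatellite loci with 10-31 alleles each):

* :func:`simulate_hierarchical` — island-model differentiation: ancestral
  broken-stick allele frequencies drift into cluster frequencies and then
  population frequencies via the multi-allele Balding-Nichols (Dirichlet)
  model, giving closed-form control of the expected fixation indices.
* :func:`simulate_stepping_stone` — distance-driven differentiation: a
  drift chain along the spatial arrangement whose step size grows with
  inter-population distance and jumps across planted barriers.

Heterozygote excess (negative FIS) is induced phenomenologically: a tuned
fraction of genotype draws is forced to carry four distinct alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import PLOIDY, Genotype, GenotypeMatrix, Locus

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_hierarchical",
    "simulate_stepping_stone",
    "survey_shape_config",
    "add_outgroup",
]


@dataclass
class SimulationConfig:
    """Generator settings; defaults follow the emulated survey's shape."""

    n_clusters: int = 5
    populations_per_cluster: tuple[int, ...] = (1, 2, 2, 2, 2)
    individuals_per_population: tuple[int, ...] = (11, 13, 17, 13, 21, 13, 16, 19, 6)
    n_loci: int = 8
    alleles_per_locus: tuple[int, int] = (10, 31)
    motif_lengths: tuple[int, ...] = (3, 3, 3, 4, 4, 3, 3, 4)
    f_ct: float = 0.12  # cluster-level drift
    f_sc: float = 0.05  # population-level drift within clusters
    ancestral_concentration: float = 0.45  # Dirichlet evenness of ancestral freqs
    fis_target: float = -0.19
    ibd_strength: float = 0.0  # stepping-stone drift per km (chain model)
    barrier_effect: float = 0.0  # extra drift when the chain crosses a barrier
    barriers_between: tuple[tuple[str, str], ...] = ()  # cluster-label pairs
    coordinates: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.f_sc < 1 and 0 <= self.f_ct < 1):
            raise ValueError("drift parameters must lie in [0, 1)")
        if len(self.populations_per_cluster) != self.n_clusters:
            raise ValueError("populations_per_cluster length must equal n_clusters")
        if sum(self.populations_per_cluster) != len(self.individuals_per_population):
            raise ValueError("individuals_per_population length must equal total populations")
        if min(self.individuals_per_population) < 1:
            raise ValueError("populations must have at least one individual")


@dataclass
class SyntheticTruth:
    ancestral_freqs: list[dict[int, float]]  # per locus: allele -> frequency
    population_freqs: dict[str, list[dict[int, float]]]
    cluster_of: dict[str, str]  # population -> cluster
    coordinates: dict[str, tuple[float, float]]
    expected_fst: float  # frequency-based global FST of the realised freqs
    barriers_between: tuple[tuple[str, str], ...] = ()
    config: SimulationConfig | None = None


# default island-style coordinate layout (four island groups, decimal degrees)
_SURVEY_COORDS = {
    "FACA": (38.584, -28.713),
    "PIAP": (38.533, -28.468),
    "PICA": (38.482, -28.381),
    "PIGM": (38.441, -28.265),
    "PISM": (38.470, -28.205),
    "TERC": (38.729, -27.303),
    "TESG": (38.695, -27.196),
    "SMLC": (37.842, -25.788),
    "SMMC": (37.853, -25.765),
}
_SURVEY_POPS = list(_SURVEY_COORDS)
_SURVEY_CLUSTERS = {
    "FACA": "F", "PIAP": "P1", "PICA": "P1", "PIGM": "P2", "PISM": "P2",
    "TERC": "T", "TESG": "T", "SMLC": "S", "SMMC": "S",
}


def survey_shape_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-shape preset: 5 clusters / 9 populations /
    129 tetraploid individuals / 8 loci, island-style coordinates, strong
    hierarchical drift and heterozygote excess."""
    cfg = dict(
        coordinates=dict(_SURVEY_COORDS),
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def _default_layout(cfg: SimulationConfig, pop_names: list[str], cluster_of: dict[str, str], rng) -> dict:
    """Cluster centroids on a circle, populations scattered around them."""
    if cfg.coordinates is not None:
        return dict(cfg.coordinates)
    clusters = list(dict.fromkeys(cluster_of.values()))
    coords = {}
    for ci, c in enumerate(clusters):
        ang = 2 * np.pi * ci / len(clusters)
        base = (38.0 + 1.5 * np.sin(ang), -27.0 + 1.5 * np.cos(ang))
        for p in [p for p in pop_names if cluster_of[p] == c]:
            coords[p] = (
                base[0] + float(rng.normal(scale=0.05)),
                base[1] + float(rng.normal(scale=0.05)),
            )
    return coords


def _make_loci(cfg: SimulationConfig, rng) -> tuple[list[Locus], list[np.ndarray], list[np.ndarray]]:
    """Loci with allele-size lattices and broken-stick ancestral frequencies."""
    loci, sizes_per_locus, anc = [], [], []
    motifs = list(cfg.motif_lengths)
    while len(motifs) < cfg.n_loci:
        motifs.append(motifs[len(motifs) % max(len(cfg.motif_lengths), 1)] if cfg.motif_lengths else 3)
    for l in range(cfg.n_loci):
        n_alleles = int(rng.integers(cfg.alleles_per_locus[0], cfg.alleles_per_locus[1] + 1))
        motif = motifs[l]
        lo = int(rng.integers(100, 300))
        sizes = lo + motif * np.arange(n_alleles)
        loci.append(Locus(f"L{l+1:02d}", motif, (int(sizes[0]), int(sizes[-1]) + motif)))
        sizes_per_locus.append(sizes)
        anc.append(rng.dirichlet(np.full(n_alleles, cfg.ancestral_concentration)))
    return loci, sizes_per_locus, anc


def _drift(freqs: np.ndarray, f: float, rng) -> np.ndarray:
    """Balding-Nichols generalisation: Dirichlet(p (1-F)/F) around p."""
    if f <= 0:
        return freqs.copy()
    lam = (1.0 - f) / f
    alpha = np.maximum(freqs * lam, 1e-6)
    return rng.dirichlet(alpha)


def _forced_marginal(p: np.ndarray, rng, m: int = 400) -> np.ndarray:
    """Marginal per-copy allele distribution of weighted sampling without
    replacement (four distinct alleles), estimated by the Gumbel top-k trick."""
    keys = np.log(p + 1e-300)[None, :] + rng.gumbel(size=(m, len(p)))
    top = np.argpartition(-keys, PLOIDY - 1, axis=1)[:, :PLOIDY]
    counts = np.bincount(top.ravel(), minlength=len(p)).astype(float)
    return counts / counts.sum()


def _solve_w(p: np.ndarray, u: np.ndarray, fis_target: float) -> float:
    """Mixture weight w of forced-distinct draws giving inbreeding fis_target.

    Within-individual identity Q_ind(w) = (1-w) sum p^2 (forced draws carry
    four distinct alleles); between-individual identity Q_pop(w) =
    sum ((1-w) p + w u)^2 with u the forced-draw marginal. Fi(w) =
    (Q_ind - Q_pop) / (1 - Q_pop) is solved by bisection on [0, 1]; the
    infeasible case (target below Fi(1)) returns w = 1.
    """
    q = float(p @ p)

    def fi(w: float) -> float:
        q_ind = (1.0 - w) * q
        mix = (1.0 - w) * p + w * u
        q_pop = float(mix @ mix)
        return (q_ind - q_pop) / (1.0 - q_pop) if q_pop < 1.0 else 0.0

    if fis_target >= 0 or q >= 1.0:
        return 0.0
    if fi(1.0) > fis_target:
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = (lo + hi) / 2
        if fi(mid) > fis_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _feasible_fis(pop_freqs: dict[str, list[np.ndarray]], rng) -> float:
    """Most negative FIS reachable by forcing all draws to distinct alleles."""
    vals = []
    for freq_list in pop_freqs.values():
        for p in freq_list:
            if np.count_nonzero(p > 0) < PLOIDY:
                vals.append(0.0)
                continue
            u = _forced_marginal(p, rng)
            q_pop = float(u @ u)
            vals.append(-q_pop / (1.0 - q_pop) if q_pop < 1.0 else 0.0)
    return float(np.mean(vals)) if vals else 0.0


def _sample_population(pop_freqs, sizes_per_locus, n_ind, prefix, fis_target, rng):
    names = [f"{prefix}_{k+1:02d}" for k in range(n_ind)]
    rows_by_locus = []
    for l, p in enumerate(pop_freqs):
        if fis_target < 0 and np.count_nonzero(p > 0) >= PLOIDY:
            u = _forced_marginal(p, rng)
            w = _solve_w(p, u, fis_target)
        else:
            w = 0.0
        forced = rng.random(n_ind) < w
        idx = np.empty((n_ind, PLOIDY), dtype=int)
        n_f = int(forced.sum())
        if n_f:
            keys = np.log(p + 1e-300)[None, :] + rng.gumbel(size=(n_f, len(p)))
            idx[forced] = np.argpartition(-keys, PLOIDY - 1, axis=1)[:, :PLOIDY]
        if n_f < n_ind:
            idx[~forced] = rng.choice(len(p), size=(n_ind - n_f, PLOIDY), p=p)
        sizes = sizes_per_locus[l]
        rows_by_locus.append([
            Genotype(tuple(int(sizes[i]) for i in sorted(draw)), dosage_known=True)
            for draw in idx
        ])
    rows = [[rows_by_locus[l][k] for l in range(len(pop_freqs))] for k in range(n_ind)]
    return names, rows


def _freq_fst(pop_freqs: dict[str, list[np.ndarray]]) -> float:
    """Frequency-based global FST = (HT - HS)/HT of the realised frequencies."""
    pops = list(pop_freqs)
    L = len(pop_freqs[pops[0]])
    ht_all, hs_all = [], []
    for l in range(L):
        mat = np.stack([pop_freqs[p][l] for p in pops])
        hs = float(np.mean(1.0 - (mat**2).sum(axis=1)))
        pbar = mat.mean(axis=0)
        ht = float(1.0 - pbar @ pbar)
        ht_all.append(ht)
        hs_all.append(hs)
    ht, hs = np.mean(ht_all), np.mean(hs_all)
    return float((ht - hs) / ht) if ht > 0 else 0.0


def _assemble(cfg, pop_names, cluster_of, pop_freqs, sizes_per_locus, loci, anc, rng):
    coords = _default_layout(cfg, pop_names, cluster_of, rng)
    individuals, cells, population_of = [], [], {}
    feasible = _feasible_fis(pop_freqs, rng)
    if cfg.fis_target < feasible - 1e-9:
        raise ValueError(
            f"fis_target={cfg.fis_target} infeasible; most negative reachable is {feasible:.3f}"
        )
    for pi, pop in enumerate(pop_names):
        names, rows = _sample_population(
            pop_freqs[pop], sizes_per_locus,
            cfg.individuals_per_population[pi], pop, cfg.fis_target, rng,
        )
        individuals.extend(names)
        cells.extend(rows)
        population_of.update({n: pop for n in names})
    gm = GenotypeMatrix(individuals, loci, cells, population_of, coords)
    truth = SyntheticTruth(
        ancestral_freqs=[
            {int(s): float(f) for s, f in zip(sizes_per_locus[l], anc[l])}
            for l in range(cfg.n_loci)
        ],
        population_freqs={
            p: [
                {int(s): float(f) for s, f in zip(sizes_per_locus[l], pop_freqs[p][l])}
                for l in range(cfg.n_loci)
            ]
            for p in pop_names
        },
        cluster_of=cluster_of,
        coordinates=coords,
        expected_fst=_freq_fst(pop_freqs),
        barriers_between=cfg.barriers_between,
        config=cfg,
    )
    return gm, truth


def _pop_names(cfg: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    if (
        cfg.coordinates is not None
        and list(cfg.coordinates) == _SURVEY_POPS
        and sum(cfg.populations_per_cluster) == 9
    ):
        return list(_SURVEY_POPS), dict(_SURVEY_CLUSTERS)
    names, cluster_of = [], {}
    k = 0
    for ci, npop in enumerate(cfg.populations_per_cluster):
        for _ in range(npop):
            name = f"C{ci+1}P{k+1}"
            names.append(name)
            cluster_of[name] = f"C{ci+1}"
            k += 1
    return names, cluster_of


def simulate_hierarchical(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Hierarchical-island dataset: two nested levels of Dirichlet drift.

    Fully reproducible given ``cfg.seed``; the returned truth records the
    realised frequencies and the frequency-based global FST.
    """
    rng = np.random.default_rng(cfg.seed)
    loci, sizes_per_locus, anc = _make_loci(cfg, rng)
    pop_names, cluster_of = _pop_names(cfg)
    clusters = list(dict.fromkeys(cluster_of.values()))
    cluster_freqs = {
        c: [_drift(anc[l], cfg.f_ct, rng) for l in range(cfg.n_loci)] for c in clusters
    }
    pop_freqs = {
        p: [_drift(cluster_freqs[cluster_of[p]][l], cfg.f_sc, rng) for l in range(cfg.n_loci)]
        for p in pop_names
    }
    return _assemble(cfg, pop_names, cluster_of, pop_freqs, sizes_per_locus, loci, anc, rng)


def simulate_stepping_stone(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Stepping-stone dataset: a spatial drift chain.

    Populations are ordered along their first spatial coordinate axis;
    frequencies perform a Dirichlet random walk whose per-step drift is
    ``ibd_strength`` per 100 km of separation, boosted by ``barrier_effect``
    whenever the step crosses a planted barrier (a pair of cluster labels in
    ``cfg.barriers_between``). Expected genetic distance therefore grows
    monotonically with chain distance.
    """
    rng = np.random.default_rng(cfg.seed)
    loci, sizes_per_locus, anc = _make_loci(cfg, rng)
    pop_names, cluster_of = _pop_names(cfg)
    coords = _default_layout(cfg, pop_names, cluster_of, rng)
    # order along the dominant spatial axis (longitude for archipelago layouts)
    order = sorted(pop_names, key=lambda p: (coords[p][1], coords[p][0]))
    pop_freqs: dict[str, list[np.ndarray]] = {}
    barrier_pairs = {frozenset(b) for b in cfg.barriers_between}
    prev = None
    for p in order:
        if prev is None:
            pop_freqs[p] = [_drift(anc[l], min(cfg.f_sc + 1e-6, 0.5), rng) for l in range(cfg.n_loci)]
        else:
            d_km = float(
                np.hypot(
                    (coords[p][0] - coords[prev][0]) * 111.0,
                    (coords[p][1] - coords[prev][1]) * 111.0 * np.cos(np.radians(coords[p][0])),
                )
            )
            f = cfg.ibd_strength * d_km / 100.0
            if frozenset((cluster_of[p], cluster_of[prev])) in barrier_pairs:
                f += cfg.barrier_effect
            f = float(np.clip(f, 1e-6, 0.8))
            pop_freqs[p] = [_drift(pop_freqs[prev][l], f, rng) for l in range(cfg.n_loci)]
        prev = p
    cfg2 = SimulationConfig(**{**cfg.__dict__, "coordinates": coords})
    return _assemble(cfg2, pop_names, cluster_of, pop_freqs, sizes_per_locus, loci, anc, rng)


def add_outgroup(
    gm: GenotypeMatrix,
    truth: SyntheticTruth,
    n_individuals: int = 5,
    divergence: float = 0.6,
    seed: int = 1,
) -> GenotypeMatrix:
    """Append a strongly diverged outgroup population (an ordination fixture
    standing in for congener samples)."""
    rng = np.random.default_rng(seed)
    loci = gm.loci
    sizes = [np.array(sorted(truth.ancestral_freqs[l])) for l in range(len(loci))]
    anc = [
        np.array([truth.ancestral_freqs[l][int(s)] for s in sizes[l]])
        for l in range(len(loci))
    ]
    out_freqs = [_drift(anc[l], divergence, rng) for l in range(len(loci))]
    names, rows = _sample_population(out_freqs, sizes, n_individuals, "OUT", 0.0, rng)
    individuals = gm.individuals + names
    cells = gm.cells + rows
    population_of = dict(gm.population_of, **{n: "OUT" for n in names})
    coords = dict(gm.coordinates or {})
    if coords:
        coords["OUT"] = (max(la for la, _ in coords.values()) + 5.0,
                         max(lo for _, lo in coords.values()) + 5.0)
    return GenotypeMatrix(individuals, loci, cells, population_of, coords or None)
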