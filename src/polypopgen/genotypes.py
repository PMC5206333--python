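"""Data model and I/O for tetraploid microsatellite (SSR) genotypes.

Alleles are identified by fragment size in base pairs. A tetraploid genotype
carries four gene copies; electropherograms often show fewer than four
distinct peaks, in which case the copy number (dosage) of each distinct
allele is unknown. We therefore distinguish *dosage-known* genotypes (four
sizes counted with multiplicity) from *dosage-ambiguous* ones (only the
distinct allele set is known). Downstream statistics declare explicitly how
they resolve the ambiguity; this module never invents dosage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PLOIDY = 4
STRUCTURE_MISSING = -9


class GenotypeError(ValueError):
    """Raised on invalid genotype data."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    motif_length is the repeat-unit length in bp (e.g. 3 for a TTC repeat);
    size_range is the (min, max) fragment size in bp.
    """

    name: str
    motif_length: int
    size_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise GenotypeError(f"locus {self.name}: motif_length must be >= 1")
        if self.size_range[0] >= self.size_range[1]:
            raise GenotypeError(f"locus {self.name}: size_range min must be < max")

    def repeat_count(self, size: float) -> float:
        """Allele size expressed in repeat units, anchored at the range minimum.

        Only differences between repeat counts are meaningful (Bruvo distance
        uses them); the anchor is arbitrary. A warning is logged when a size
        is more than 0.2 repeat units off the motif lattice.
        """
        x = (size - self.size_range[0]) / self.motif_length
        if abs(x - round(x)) > 0.2:
            log.warning(
                "locus %s: allele size %s is %.2f repeat units off the motif lattice",
                self.name, size, abs(x - round(x)),
            )
        return float(round(x))


@dataclass(frozen=True)
class Genotype:
    """One individual's genotype at one locus.

    ``alleles`` is a sorted tuple of allele sizes; for a dosage-known genotype
    it has exactly four entries counted with multiplicity, otherwise it holds
    the 1-3 distinct sizes observed. The empty tuple encodes missing data.
    """

    alleles: tuple[int, ...]
    dosage_known: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        if self.missing:
            object.__setattr__(self, "dosage_known", False)
            return
        distinct = set(self.alleles)
        if not 1 <= len(distinct) <= PLOIDY:
            raise GenotypeError(f"genotype must carry 1-{PLOIDY} distinct alleles, got {distinct}")
        if self.dosage_known and len(self.alleles) != PLOIDY:
            raise GenotypeError("dosage-known genotype must have exactly 4 copies")
        if not self.dosage_known and len(self.alleles) != len(distinct):
            raise GenotypeError("dosage-ambiguous genotype must list distinct alleles only")
        if not self.dosage_known and len(distinct) == PLOIDY:
            # four distinct alleles fix the dosage trivially
            object.__setattr__(self, "dosage_known", True)

    @classmethod
    def from_sizes(cls, sizes) -> "Genotype":
        """Build from a raw list of observed sizes: 4 sizes = dosage known."""
        sizes = tuple(sorted(int(s) for s in sizes))
        if not sizes:
            return cls(())
        if len(sizes) == PLOIDY:
            return cls(sizes, dosage_known=True)
        return cls(tuple(sorted(set(sizes))))

    @property
    def missing(self) -> bool:
        return len(self.alleles) == 0

    @property
    def distinct(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.alleles)))

    def completions(self) -> list[tuple[int, ...]]:
        """All dosage completions to four copies consistent with the distinct set.

        A dosage-known genotype has a single completion (itself). For k < 4
        distinct alleles every composition of 4 copies with each allele
        appearing at least once is returned.
        """
        if self.missing:
            raise GenotypeError("cannot complete a missing genotype")
        if self.dosage_known:
            return [self.alleles]
        distinct = self.distinct
        k = len(distinct)
        out = []
        for counts in _compositions(PLOIDY, k):
            geno = []
            for a, c in zip(distinct, counts):
                geno.extend([a] * c)
            out.append(tuple(geno))
        return out

    def copy_counts(self) -> dict[int, float]:
        """Gene-copy counts per allele under the equal-split convention.

        Dosage-known cells use their true multiplicities; ambiguous cells
        split the four copies evenly over the distinct alleles (4/k each).
        """
        if self.missing:
            return {}
        if self.dosage_known:
            return {a: float(self.alleles.count(a)) for a in self.distinct}
        w = PLOIDY / len(self.distinct)
        return {a: w for a in self.distinct}


def _compositions(total: int, k: int) -> list[tuple[int, ...]]:
    """Compositions of `total` into k positive parts, lexicographic order."""
    if k == 1:
        return [(total,)]
    out = []
    for first in range(1, total - k + 2):
        for rest in _compositions(total - first, k - 1):
            out.append((first,) + rest)
    return out


@dataclass
class GenotypeMatrix:
    """Individuals x loci table of tetraploid genotypes with population labels."""

    individuals: list[str]
    loci: list[Locus]
    cells: list[list[Genotype]]  # [individual][locus]
    population_of: dict[str, str]
    coordinates: dict[str, tuple[float, float]] | None = None  # population -> (lat, lon)

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            dupes = {i for i in self.individuals if self.individuals.count(i) > 1}
            raise GenotypeError(f"duplicate individual labels: {sorted(dupes)}")
        if len(self.cells) != len(self.individuals):
            raise GenotypeError("cells must have one row per individual")
        for row in self.cells:
            if len(row) != len(self.loci):
                raise GenotypeError("cells must be rectangular (one column per locus)")
        missing_pop = [i for i in self.individuals if i not in self.population_of]
        if missing_pop:
            raise GenotypeError(f"individuals without population: {missing_pop}")
        self.validate_sizes()

    def validate_sizes(self) -> None:
        offenders = []
        for i, ind in enumerate(self.individuals):
            for l, locus in enumerate(self.loci):
                g = self.cells[i][l]
                if g.missing:
                    continue
                lo, hi = locus.size_range
                for a in g.distinct:
                    if not lo <= a <= hi:
                        offenders.append((ind, locus.name, a))
        if offenders:
            raise GenotypeError(f"allele sizes outside locus size_range: {offenders[:20]}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for ind in self.individuals:
            p = self.population_of[ind]
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def individuals_of(self, population: str) -> list[str]:
        return [i for i in self.individuals if self.population_of[i] == population]

    def cell(self, individual: str, locus: str) -> Genotype:
        i = self.individuals.index(individual)
        l = [x.name for x in self.loci].index(locus)
        return self.cells[i][l]


@dataclass
class DominantMatrix:
    """Binary individuals x band (locus, allele-size) presence/absence matrix."""

    individuals: list[str]
    bands: list[tuple[str, int]]
    values: np.ndarray  # int8, individuals x bands
    missing: np.ndarray  # bool, True where the band's locus is missing for that row
    population_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != (len(self.individuals), len(self.bands)):
            raise GenotypeError("dominant matrix shape mismatch")
        if self.missing.shape != self.values.shape:
            raise GenotypeError("missing mask shape mismatch")
        ok = np.isin(self.values[~self.missing], [0, 1]).all()
        if not ok:
            raise GenotypeError("dominant values must be 0/1")
        observed = (self.values == 1) & ~self.missing
        if len(self.individuals) and not observed.any(axis=0).all():
            raise GenotypeError("every band must be present in at least one individual")

    @property
    def band_loci(self) -> list[str]:
        return [b[0] for b in self.bands]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{l}:{a}" for l, a in self.bands]
        df = pd.DataFrame(self.values.astype(float), index=self.individuals, columns=cols)
        df[self.missing] = np.nan
        return df


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def infer_loci(names, allele_sets) -> list[Locus]:
    """Infer locus metadata from observed alleles.

    motif_length = GCD of pairwise size differences (1 if monomorphic);
    size_range padded to the observed min/max.
    """
    loci = []
    for name, sizes in zip(names, allele_sets):
        sizes = sorted(sizes)
        if len(sizes) >= 2:
            motif = 0
            for a, b in zip(sizes, sizes[1:]):
                motif = math.gcd(motif, b - a)
            motif = max(motif, 1)
            lo, hi = sizes[0], sizes[-1]
        else:
            motif = 1
            lo = sizes[0] if sizes else 100
            hi = lo + 1
        loci.append(Locus(name, motif, (lo, hi + (0 if hi > lo else 1))))
    return loci


def _parse_cell(raw) -> tuple[Genotype, bool]:
    """Parse one wide-format cell; returns (genotype, parse_failed)."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return Genotype(()), False
    s = str(raw).strip()
    if s in ("", "NA", "na", "-", "?", "-9"):
        return Genotype(()), False
    try:
        sizes = [int(float(tok)) for tok in s.replace("|", "/").split("/") if tok.strip()]
    except ValueError:
        return Genotype(()), True
    if not sizes or len(sizes) > PLOIDY:
        return Genotype(()), True
    return Genotype.from_sizes(sizes), False


def read_genotypes(path, format: str = "wide", loci: list[Locus] | None = None) -> GenotypeMatrix:
    """Read a tabular genotype file.

    format="wide": columns ``individual, population, <locus1>, <locus2>, ...``
    where each locus cell is a ``/``-separated list of up to four allele sizes
    (four sizes = dosage known; fewer = dosage-ambiguous; empty = missing).

    format="long": columns ``individual, population, locus, allele`` with one
    row per observed gene copy.

    Unparseable allele entries become missing cells (a warning reports the
    count); duplicate individual labels are a hard error.
    """
    if format == "wide":
        df = pd.read_csv(path, dtype=str)
        ind_col, pop_col = df.columns[0], df.columns[1]
        locus_names = list(df.columns[2:])
        individuals = df[ind_col].tolist()
        population_of = dict(zip(individuals, df[pop_col]))
        n_bad = 0
        rows = []
        for _, rec in df.iterrows():
            row = []
            for ln in locus_names:
                g, bad = _parse_cell(rec[ln])
                n_bad += bad
                row.append(g)
            rows.append(row)
    elif format == "long":
        df = pd.read_csv(path)
        df.columns = [c.lower() for c in df.columns]
        individuals = list(dict.fromkeys(df["individual"].astype(str)))
        population_of = {
            str(i): str(p) for i, p in zip(df["individual"], df["population"])
        }
        locus_names = list(dict.fromkeys(df["locus"].astype(str)))
        n_bad = 0
        cell_sizes: dict[tuple[str, str], list[int]] = {}
        for _, rec in df.iterrows():
            try:
                a = int(float(rec["allele"]))
            except (ValueError, TypeError):
                n_bad += 1
                continue
            cell_sizes.setdefault((str(rec["individual"]), str(rec["locus"])), []).append(a)
        rows = [
            [Genotype.from_sizes(cell_sizes.get((i, ln), [])) for ln in locus_names]
            for i in individuals
        ]
    else:
        raise ValueError(f"unknown genotype dialect: {format!r}")

    if n_bad:
        log.warning("%d unparseable allele entries treated as missing", n_bad)
    if loci is None:
        allele_sets = [
            {a for row in rows for a in row[l].distinct} for l in range(len(locus_names))
        ]
        loci = infer_loci(locus_names, allele_sets)
    return GenotypeMatrix(individuals, loci, rows, population_of)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the wide-CSV dialect understood by :func:`read_genotypes`."""
    recs = []
    for i, ind in enumerate(gm.individuals):
        rec = {"individual": ind, "population": gm.population_of[ind]}
        for l, locus in enumerate(gm.loci):
            g = gm.cells[i][l]
            rec[locus.name] = "" if g.missing else "/".join(str(a) for a in g.alleles)
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False)


def read_coordinates(path) -> dict[str, tuple[float, float]]:
    """Sidecar CSV of population coordinates: columns population, lat, lon."""
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    return {str(r["population"]): (float(r["lat"]), float(r["lon"])) for _, r in df.iterrows()}


def write_coordinates(coords: dict[str, tuple[float, float]], path) -> None:
    pd.DataFrame(
        [{"population": p, "lat": la, "lon": lo} for p, (la, lo) in coords.items()]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Derived encodings and filters
# ---------------------------------------------------------------------------

def to_dominant(gm: GenotypeMatrix) -> DominantMatrix:
    """Collapse co-dominant genotypes to a binary band-presence matrix.

    One band per (locus, allele size) observed anywhere; bands ordered by
    locus order then ascending size. Presence means the allele occurs in the
    individual's distinct set; a missing cell masks all of that locus's bands
    for that row.
    """
    if not gm.individuals:
        raise GenotypeError("empty genotype matrix")
    bands: list[tuple[str, int]] = []
    for l, locus in enumerate(gm.loci):
        sizes = sorted({a for row in gm.cells for a in row[l].distinct})
        bands.extend((locus.name, a) for a in sizes)
    band_index = {b: j for j, b in enumerate(bands)}
    values = np.zeros((len(gm.individuals), len(bands)), dtype=np.int8)
    missing = np.zeros_like(values, dtype=bool)
    for i in range(len(gm.individuals)):
        for l, locus in enumerate(gm.loci):
            g = gm.cells[i][l]
            cols = [band_index[(locus.name, a)] for a in sorted(
                {b for row in gm.cells for b in row[l].distinct})]
            if g.missing:
                missing[i, cols] = True
            else:
                for a in g.distinct:
                    values[i, band_index[(locus.name, a)]] = 1
    return DominantMatrix(
        list(gm.individuals), bands, values, missing, dict(gm.population_of)
    )


def filter_small_populations(gm: GenotypeMatrix, min_n: int) -> tuple[GenotypeMatrix, list[str]]:
    """Drop populations with fewer than ``min_n`` individuals.

    Returns the filtered matrix and the list of removed population labels.
    Retained genotypes are carried over unchanged.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    sizes = gm.population_sizes()
    removed = sorted(p for p, n in sizes.items() if n < min_n)
    if len(removed) == len(sizes):
        raise GenotypeError(f"min_n={min_n} removes every population")
    keep_idx = [
        i for i, ind in enumerate(gm.individuals)
        if gm.population_of[ind] not in removed
    ]
    individuals = [gm.individuals[i] for i in keep_idx]
    cells = [gm.cells[i] for i in keep_idx]
    population_of = {i: gm.population_of[i] for i in individuals}
    coords = None
    if gm.coordinates is not None:
        coords = {p: xy for p, xy in gm.coordinates.items() if p not in removed}
    out = GenotypeMatrix(individuals, list(gm.loci), cells, population_of, coords)
    if removed:
        log.info("removed %d populations below n=%d: %s", len(removed), min_n, removed)
    return out, removed


# ---------------------------------------------------------------------------
# STRUCTURE interchange format
# ---------------------------------------------------------------------------

def write_structure_file(dm: DominantMatrix, path) -> None:
    """Emit a STRUCTURE-format raw data file for the binary band matrix.

    One row per individual (bands coded as haploid biallelic loci 0/1),
    missing data as -9, second column is an integer population code. A header
    row carries the band names.
    """
    pops = list(dict.fromkeys(dm.population_of.get(i, "1") for i in dm.individuals))
    pop_code = {p: k + 1 for k, p in enumerate(pops)}
    with open(path, "w") as fh:
        fh.write("\t".join(f"{l}:{a}" for l, a in dm.bands) + "\n")
        for i, ind in enumerate(dm.individuals):
            vals = [
                str(STRUCTURE_MISSING) if dm.missing[i, j] else str(int(dm.values[i, j]))
                for j in range(len(dm.bands))
            ]
            fh.write("\t".join([ind, str(pop_code[dm.population_of.get(ind, "1")])] + vals) + "\n")


def read_structure_file(path, population_names: dict[int, str] | None = None) -> DominantMatrix:
    """Read back a file written by :func:`write_structure_file`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        bands = []
        for tok in header:
            l, a = tok.rsplit(":", 1)
            bands.append((l, int(a)))
        individuals, pops, rows = [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            individuals.append(parts[0])
            pops.append(int(parts[1]))
            rows.append([int(v) for v in parts[2:]])
    arr = np.array(rows, dtype=np.int16)
    missing = arr == STRUCTURE_MISSING
    values = np.where(missing, 0, arr).astype(np.int8)
    if population_names is None:
        population_names = {c: str(c) for c in sorted(set(pops))}
    population_of = {i: population_names[c] for i, c in zip(individuals, pops)}
    return DominantMatrix(individuals, bands, values, missing, population_of)
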