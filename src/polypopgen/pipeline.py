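"""End-to-end orchestration of the analysis pipeline.

Runs import -> population filter -> diversity -> Bruvo distances -> PCoA ->
admixture scan (delta-K, replicate alignment) -> AMOVA / pairwise FST ->
Monmonier barriers -> Mantel HIM/SSM protocol -> beta-regression model
ladders, writing tabular reports, figures and a machine-readable summary.
Stages whose inputs are unavailable (e.g. no coordinates) are skipped with a
notice; every stochastic stage has an explicit seed recorded in the output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import admixture as adx
from . import amova as amv
from . import barriers as bar
from . import distances as dst
from . import diversity as dvs
from . import genotypes as gio
from . import ibd
from . import ordination as ordn
from . import simulate as sim

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; serialised into the output for provenance."""

    genotypes: str | None = None  # path; None with preset -> simulate
    genotype_format: str = "wide"
    coordinates: str | None = None
    preset: str | None = None  # "survey-shape" simulates the default survey shape
    out_dir: str = "polypopgen_out"
    min_population_size: int = 6
    dosage_policy: str = "equal-split"
    permutations: int = 999
    mantel_permutations: int = 4999
    max_barriers: int = 9
    mcmc: adx.McmcSettings = field(default_factory=lambda: adx.McmcSettings(k_range=(1, 8)))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mcmc = raw.pop("mcmc", None)
        cfg = cls(**raw)
        if mcmc:
            if "k_range" in mcmc:
                mcmc["k_range"] = tuple(mcmc["k_range"])
            cfg.mcmc = adx.McmcSettings(**mcmc)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def stage_hash(self, *parts: str) -> str:
        payload = json.dumps([self.to_dict(), list(parts)], sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineResult(dict):
    """Dict of stage outputs with attribute access for the common ones."""

    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError as e:  # pragma: no cover
            raise AttributeError(name) from e


def _population_clusters(q: adx.QMatrix, gm: gio.GenotypeMatrix) -> dict[str, str]:
    """Assign each population the majority hard cluster of its individuals."""
    labels = q.hard_labels()
    out = {}
    for pop in gm.populations:
        idx = [q.individuals.index(i) for i in gm.individuals_of(pop)]
        vals, counts = np.unique(labels[idx], return_counts=True)
        out[pop] = f"K{int(vals[np.argmax(counts)]) + 1}"
    return out


def run_all(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    result = PipelineResult()
    notices: list[str] = []

    # ---- import -----------------------------------------------------------
    if config.genotypes:
        gm = gio.read_genotypes(config.genotypes, config.genotype_format)
        if config.coordinates:
            gm.coordinates = gio.read_coordinates(config.coordinates)
    elif config.preset == "survey-shape":
        gm, truth = sim.simulate_hierarchical(sim.survey_shape_config(seed=config.seed))
        result["truth"] = truth
    else:
        raise ValueError("config needs either a genotypes path or preset='survey-shape'")

    gm, removed = gio.filter_small_populations(gm, config.min_population_size)
    if removed:
        notices.append(f"removed populations below n={config.min_population_size}: {removed}")
    gio.write_genotypes(gm, out / "genotypes_filtered.csv")
    result["genotypes"] = gm

    # ---- diversity --------------------------------------------------------
    report = dvs.diversity_report(
        gm, config.dosage_policy, permutations=config.permutations, seed=config.seed
    )
    report.to_frame().to_csv(out / "diversity.csv")
    (out / "diversity_settings.json").write_text(json.dumps({
        "permutations": config.permutations, "seed": config.seed,
        "dosage_policy": config.dosage_policy, "rarefaction_g": report.rarefaction_g,
    }, indent=2))
    result["diversity"] = report

    # ---- distances & ordination ------------------------------------------
    bruvo = dst.bruvo_matrix(gm)
    bruvo.to_csv(out / "bruvo.csv")
    pco = ordn.pcoa(bruvo)
    pco.to_frame(4).to_csv(out / "pcoa_coordinates.csv")
    _plot_pcoa(pco, gm, out / "pcoa.png")
    result["bruvo"] = bruvo
    result["pcoa"] = pco

    dm = gio.to_dominant(gm)
    gio.write_structure_file(dm, out / "structure_input.str")
    nei = dst.nei_distance(dm)
    nei.to_csv(out / "nei.csv")
    result["dominant"] = dm
    result["nei"] = nei

    # ---- admixture --------------------------------------------------------
    stage_key = config.stage_hash("admixture")
    runs = adx.admixture_scan(dm, dataclasses.replace(config.mcmc, seed=config.seed))
    dk = adx.evanno_from_runs(runs)
    dk.to_csv(out / "delta_k.csv")
    best_k = dk.attrs["best_k"] or config.mcmc.k_range[0]
    consensus, similarity = adx.align_runs(runs[best_k])
    consensus.to_frame().to_csv(out / f"q_consensus_K{best_k}.csv")
    _plot_structure(consensus, gm, out / "structure_bars.png")
    manifest["admixture"] = stage_key
    result["delta_k"] = dk
    result["best_k"] = best_k
    result["q_consensus"] = consensus
    result["run_similarity"] = similarity

    # ---- AMOVA / FST ------------------------------------------------------
    clusters = _population_clusters(consensus, gm)
    result["clusters"] = clusters
    am = amv.amova_three_level(
        dm, clusters=clusters, permutations=config.permutations, seed=config.seed
    )
    am.table.to_csv(out / "amova.csv")
    pw = amv.pairwise_fst(dm, permutations=min(config.permutations, 199), seed=config.seed)
    pw.combined_table().to_csv(out / "fst_nm.csv")
    result["amova"] = am
    result["pairwise_fst"] = pw

    # ---- geography-dependent stages ---------------------------------------
    if gm.coordinates and all(p in gm.coordinates for p in gm.populations):
        geo = dst.geographic_matrix(gm.coordinates, gm.populations)
        geo.to_csv(out / "geographic.csv")
        net = bar.delaunay_network(gm.coordinates, gm.populations, jitter_seed=config.seed)
        bset = bar.monmonier_barriers(net, nei, config.max_barriers)
        _write_barriers(bset, out / "barriers.json")
        result["geographic"] = geo
        result["barriers"] = bset

        protocol = ibd.him_ssm_protocol(
            nei, geo, clusters, permutations=config.mantel_permutations, seed=config.seed
        )
        protocol.to_csv(out / "mantel_protocol.csv", index=False)
        result["mantel"] = protocol

        ladders = {}
        for tag, comp in (("structure-clusters", clusters), ("barrier-order", bset)):
            ladder = ibd.build_model_ladder(nei, geo, tag, comp)
            ladder.to_frame().to_csv(out / f"ladder_{tag}.csv", index=False)
            ladders[tag] = ladder
        result["ladders"] = ladders
        _plot_ibd(nei, geo, ladders["structure-clusters"], out / "ibd.png")
    else:
        notices.append("coordinates unavailable: barrier and IBD stages skipped")

    # ---- summary ----------------------------------------------------------
    summary = {
        "n_individuals": len(gm.individuals),
        "n_populations": len(gm.populations),
        "n_loci": len(gm.loci),
        "ht": report.ht,
        "fis_multilocus": report.fis_multilocus,
        "fis_pvalue": report.fis_pvalue,
        "pa_total_pct": report.pa_total,
        "pcoa_inertia_pct_axis1": float(pco.inertia_pct[0]),
        "pcoa_inertia_pct_axis2": float(pco.inertia_pct[1]),
        "best_k": int(best_k),
        "global_fst": pw.global_fst,
        "amova_pct_within_pops": float(am.table.loc["within_pops", "percentage"]),
        "amova_pct_among_clusters": float(am.table.loc["among_clusters", "percentage"]),
        "notices": notices,
        "seed": config.seed,
    }
    if "mantel" in result:
        summary["mantel_r_genetic_geographic"] = float(result["mantel"].iloc[0]["r"])
        summary["best_aic_structure_clusters"] = float(
            result["ladders"]["structure-clusters"].best.aic
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest_path.write_text(json.dumps(manifest, indent=2))
    result["summary"] = summary
    return result


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _plot_pcoa(pco: ordn.PcoaResult, gm: gio.GenotypeMatrix, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    pops = gm.populations
    cmap = plt.get_cmap("tab10")
    for k, pop in enumerate(pops):
        idx = [pco.labels.index(i) for i in gm.individuals_of(pop)]
        ax.scatter(
            pco.coordinates[idx, 0], pco.coordinates[idx, 1],
            s=18, color=cmap(k % 10), label=pop,
        )
    ax.set_xlabel(f"PCo1 ({pco.inertia_pct[0]:.2f} %)")
    ax.set_ylabel(f"PCo2 ({pco.inertia_pct[1]:.2f} %)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_structure(q: adx.QMatrix, gm: gio.GenotypeMatrix, path) -> None:
    order = [i for pop in gm.populations for i in gm.individuals_of(pop)]
    idx = [q.individuals.index(i) for i in order]
    mat = q.q[idx]
    fig, ax = plt.subplots(figsize=(10, 2.5))
    bottom = np.zeros(len(order))
    cmap = plt.get_cmap("tab10")
    for k in range(q.K):
        ax.bar(range(len(order)), mat[:, k], bottom=bottom, width=1.0, color=cmap(k % 10))
        bottom += mat[:, k]
    ax.set_xlim(-0.5, len(order) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("q")
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_ibd(nei, geo, ladder, path) -> None:
    iu = np.triu_indices(len(nei.labels), 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(geo.reorder(nei.labels).values[iu] / 1000.0, nei.values[iu], s=20)
    ax.set_xlabel("geographic distance (km)")
    ax.set_ylabel("Nei genetic distance")
    ax.set_title(f"best model AIC={ladder.best.aic:.1f}, pseudo-R2={ladder.best.pseudo_r2:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_barriers(bset: bar.BarrierSet, path) -> None:
    payload = {
        "notice": bset.notice,
        "barriers": {
            letter: {
                "crossed": [list(e) for e in b.crossed],
                "distances": b.distances,
                "reached_boundary": b.reached_boundary,
                "closed_loop": b.closed_loop,
            }
            for letter, b in bset.orders().items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
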