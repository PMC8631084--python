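"""End-to-end orchestration: load → filter → f-statistics → graph → tree.

``run_full`` reproduces the full analysis shape on any compliant VCF +
sample sheet: outgroup-f3 table, Bonferroni-controlled f4 enumeration,
autosome-vs-X f4 contrasts on the masked X, admixture-graph fitting with
X-specific refit of the mixing weights, and an IBS neighbor-joining tree.
``demo`` first generates the nuclear-swamping scenario and then runs the
pipeline on it.  A single seed governs every stochastic stage; per-stage
seeds are derived by hashing stage labels, so stages are independently
reproducible.  Every number in the report bundle is recomputable from the
persisted intermediate tables.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture_graph as ag
from . import fstats as fs
from . import genotype_data as gd
from . import phylo_distance as pdist
from . import synthetic_data as sd

logger = logging.getLogger(__name__)


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (seed * 1_000_003 + zlib.crc32(label.encode())) % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    vcf: str
    sample_sheet: str
    class_map: str
    outgroup: str
    outdir: str
    masks: list[str] = field(default_factory=lambda: ["x_default_exclusion"])
    block_size: int = 5_000_000
    alpha: float = 0.05
    contrasts: list[tuple[str, str, str, str]] = field(default_factory=list)
    graph: str | None = None          # topology file path or "greedy"
    refit_mode: str = "alpha_and_scale"
    max_edges: int = 2
    z_stop: float = 3.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["contrasts"] = [tuple(c) for c in raw.get("contrasts", [])]
        return cls(**raw)

    def resolve_masks(self) -> list[gd.RegionMask]:
        out = []
        for m in self.masks:
            if Path(m).exists():
                out.append(gd.read_bed(m))
            else:
                out.append(gd.preset_mask(m))
        return out


def _log_stage(lines: list[str], stage: str, **info) -> None:
    msg = f"[{stage}] " + " ".join(f"{k}={v}" for k, v in info.items())
    logger.info(msg)
    lines.append(msg)


def run_full(config: PipelineConfig) -> dict:
    """Run every stage; writes TSV/JSON/Newick/DOT outputs to the run dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    report: dict = {"seed": config.seed, "outgroup": config.outgroup}

    sheet = gd.read_sample_sheet(config.sample_sheet)
    class_map = gd.read_class_map(config.class_map)
    gm = gd.read_vcf(config.vcf, sheet, class_map)
    _log_stage(log, "load", sites=gm.n_sites, samples=gm.n_samples)

    n0 = gm.n_sites
    gm = gd.filter_complete_cases(gm)
    _log_stage(log, "complete_cases", kept=gm.n_sites, dropped=n0 - gm.n_sites)

    for mask in config.resolve_masks():
        n0 = gm.n_sites
        gm = gd.apply_region_mask(gm, mask, mode="exclude")
        _log_stage(log, "mask", label=mask.label, dropped=n0 - gm.n_sites)

    table = gd.allele_counts_by_population(gm)
    has_x = bool((table.sites["chrom_class"] == "X").any())
    table_a = table.for_class("autosome")
    part_a = gd.assign_blocks(table_a.sites, config.block_size, ["autosome"])
    if has_x:
        table_x = table.for_class("X")
        part_x = gd.assign_blocks(table_x.sites, config.block_size, ["X"])
        _log_stage(log, "blocks", autosome=part_a.n_blocks, x=part_x.n_blocks)
    else:
        _log_stage(log, "blocks", autosome=part_a.n_blocks, x=0)

    # --- outgroup f3 table ------------------------------------------------
    import itertools

    pops = [p for p in table.populations if p != config.outgroup]
    f3_rows = []
    for a, b in itertools.combinations(sorted(pops), 2):
        cfg = fs.FStatConfig("f3_outgroup", (a, b, config.outgroup))
        f3_rows.append(fs.f_statistic(table_a, cfg, part_a))
    f3_df = fs.results_to_frame(f3_rows)
    f3_df.to_csv(outdir / "f3_outgroup.tsv", sep="\t", index=False)
    _log_stage(log, "f3", n=len(f3_df))

    # --- f4 enumeration ---------------------------------------------------
    if len(pops) >= 3:
        enum = fs.enumerate_f4(table_a, config.outgroup, part_a,
                               alpha=config.alpha)
        enum.to_csv(outdir / "f4_enumeration.tsv", sep="\t", index=False)
        report["n_f4_configurations"] = int(len(enum))
        report["n_f4_significant"] = int(enum["significant"].sum())
        _log_stage(log, "enumerate_f4", configs=len(enum),
                   significant=int(enum["significant"].sum()))

    # --- autosome vs X contrasts -----------------------------------------
    contrast_rows = []
    if config.contrasts and not has_x:
        raise fs.FStatError("contrast stage requires X-chromosome sites, "
                            "but none survive the masks")
    for quad in config.contrasts:
        cfg = fs.FStatConfig("f4", tuple(quad))
        cr = fs.contrast_autosome_x(table, cfg, part_a, part_x)
        contrast_rows.append({
            "config": str(cfg),
            "f4_autosome": cr.autosome.estimate, "z_autosome": cr.autosome.z,
            "f4_x": cr.x.estimate, "z_x": cr.x.z,
            "t_welch": cr.t_welch, "df_welch": cr.df_welch,
            "p_value": cr.p_value, "direction": cr.direction,
        })
        _log_stage(log, "contrast", config=str(cfg), p=f"{cr.p_value:.4g}",
                   direction=cr.direction)
    if contrast_rows:
        pd.DataFrame(contrast_rows).to_csv(outdir / "contrast_autosome_x.tsv",
                                           sep="\t", index=False)
        report["contrasts"] = contrast_rows

    # --- IBS distances and NJ tree ---------------------------------------
    dm = pdist.ibs_distance(gm)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        outdir / "ibs_distances.tsv", sep="\t")
    tree = pdist.neighbor_joining(dm)
    out_samples = sheet.loc[sheet["population"] == config.outgroup,
                            "sample_id"]
    if len(out_samples) == 1:
        tree = pdist.root_by_outgroup(tree, out_samples.iloc[0])
    tree.write(str(outdir / "nj_tree.nwk"))
    _log_stage(log, "nj_tree", taxa=len(dm.ids))

    # --- admixture graph ---------------------------------------------------
    if config.graph:
        basis = ag.fit_basis(table_a, part_a, config.outgroup)
        gseed = derive_seed(config.seed, "graph")
        if config.graph == "greedy":
            topo = tree_graph_from_f2(table_a, part_a, config.outgroup)
            fit, steps = ag.greedy_edge_addition(
                topo, table_a, part_a, max_edges=config.max_edges,
                z_stop=config.z_stop, outgroup=config.outgroup, seed=gseed)
            _log_stage(log, "graph_greedy", edges_added=len(steps),
                       worst_z=f"{fit.worst_f4[2]:.3g}")
        else:
            topo = ag.AdmixtureGraph.from_text(Path(config.graph).read_text())
            fit = ag.fit_graph(topo, basis, seed=gseed)
            ag.worst_residual(fit, table_a, part_a)
            _log_stage(log, "graph_fit", score=f"{fit.score:.4g}",
                       worst_z=f"{fit.worst_f4[2]:.3g}")
        (outdir / "graph_fitted.txt").write_text(fit.graph.to_text())
        (outdir / "graph_fitted.dot").write_text(fit.graph.to_dot())
        report["graph"] = {
            "score": fit.score,
            "worst_f4": {"config": fit.worst_f4[0],
                         "residual": fit.worst_f4[1], "z": fit.worst_f4[2]},
            "alphas": fit.alphas(),
        }
        if has_x and fit.graph.admixture_nodes():
            refit = ag.refit_admixture_on_x(
                fit, table_x, part_x, mode=config.refit_mode,
                outgroup=config.outgroup,
                seed=derive_seed(config.seed, "refit_x"))
            refit.to_csv(outdir / "x_refit.tsv", sep="\t", index=False)
            report["x_refit"] = refit.to_dict(orient="records")
            _log_stage(log, "refit_x", mode=config.refit_mode,
                       nodes=len(refit))

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=float))
    return report


def tree_graph_from_f2(table: gd.AlleleCountTable,
                       partition: gd.BlockPartition,
                       outgroup: str) -> ag.AdmixtureGraph:
    """Starting topology: neighbor joining on pairwise f2 distances.

    f2 is additive along a drift tree, so NJ on the f2 matrix recovers the
    population phylogeny; the rooted tree (outgroup rooting) becomes the
    admixture-graph skeleton with NJ branch lengths as initial drift values.
    """
    import itertools

    from skbio import DistanceMatrix

    pops = sorted(table.populations)
    D = np.zeros((len(pops), len(pops)))
    for (i, a), (j, b) in itertools.combinations(enumerate(pops), 2):
        r = fs.f_statistic(table, fs.FStatConfig("f2", (a, b)), partition)
        D[i, j] = D[j, i] = max(r.estimate, 0.0)
    tree = pdist.neighbor_joining(DistanceMatrix(D, pops))
    rooted = pdist.root_by_outgroup(tree, outgroup)
    graph = ag.AdmixtureGraph()
    counter = [0]

    def name_of(node) -> str:
        if node.name:
            return str(node.name)
        counter[0] += 1
        return f"n{counter[0]}"

    def walk(node, node_name):
        for child in node.children:
            child_name = name_of(child)
            graph.add_edge(node_name, child_name,
                           max(child.length or 0.0, 0.0))
            walk(child, child_name)

    walk(rooted, "R")
    graph.validate()
    return graph


def demo(seed: int, outdir: str | Path, strength: float = 0.02,
         duration: int = 150, make_figures: bool = True,
         plan: sd.LocusPlan | None = None, graph: str | None = "greedy"
         ) -> dict:
    """Generate the nuclear-swamping preset and run the full pipeline on it.

    Writes the simulated VCF, sample sheet, class map, and truth record,
    then the full report bundle, plus (optionally) a forest plot of the
    autosome-vs-X f4 contrast and the fitted graph in DOT form.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_seed = derive_seed(seed, "simulate")
    plan = plan or sd.LocusPlan()
    model, gm, truth = sd.nuclear_swamping_scenario(
        strength=strength, duration=duration, seed=sim_seed, plan=plan)
    sd.write_vcf(gm, outdir / "simulated.vcf")
    gm.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "class_map.tsv", "w") as fh:
        for chrom, cls in plan.class_map().items():
            fh.write(f"{chrom}\t{cls}\n")
    (outdir / "truth.json").write_text(json.dumps({
        "donor_fraction_autosome": truth.donor_fraction("C", "Dp", "autosome"),
        "donor_fraction_x": truth.donor_fraction("C", "Dp", "X"),
        "donor_fraction_mito": truth.donor_fraction("C", "Dp", "mito"),
        "strength": strength, "duration": duration, "seed": sim_seed,
    }, indent=2))

    config = PipelineConfig(
        vcf=str(outdir / "simulated.vcf"),
        sample_sheet=str(outdir / "samples.tsv"),
        class_map=str(outdir / "class_map.tsv"),
        outgroup="A",
        outdir=str(outdir),
        masks=[],  # simulated X carries no PARs
        contrasts=[("A", "B", "C", "D")],
        graph=graph,
        seed=seed,
    )
    report = run_full(config)
    report["truth"] = json.loads((outdir / "truth.json").read_text())
    if make_figures:
        try:
            _demo_figures(outdir)
        except Exception as exc:   # figures are a convenience, not a stage
            logger.warning("figure rendering skipped: %s", exc)
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=float))
    return report


def _demo_figures(outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = outdir / "contrast_autosome_x.tsv"
    if path.exists():
        df = pd.read_csv(path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 2 + 0.6 * len(df)))
        y = np.arange(len(df))
        ax.errorbar(df["f4_autosome"], y + 0.12,
                    xerr=1.96 * df["f4_autosome"] / df["z_autosome"],
                    fmt="o", label="autosomes")
        ax.errorbar(df["f4_x"], y - 0.12,
                    xerr=1.96 * df["f4_x"] / df["z_x"],
                    fmt="s", label="X")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(y, df["config"])
        ax.set_xlabel("f4 estimate (95% CI)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "contrast_forest.png", dpi=120)
        plt.close(fig)
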