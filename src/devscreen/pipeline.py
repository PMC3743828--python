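"""End-to-end pipeline: simulate -> normalize -> distances -> NDE -> gene sets.

`run_pipeline` executes every stage in dependency order, writes all
intermediate tables as TSV into the configured output directory, and
returns a :class:`RunManifest` with a SHA-256 checksum for every output
file. Identical configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distance import classical_mds, deviation_curve, distance_matrix, timing_table
from .genesets import (
    GeneSetResult,
    build_gene_sets,
    celltype_alteration_fraction,
    enrichment_test,
)
from .io import (
    CountPanel,
    GeneCatalog,
    compute_rpkm,
    mean_profiles,
    read_count_panel,
    write_count_panel,
)
from .nde import (
    estimate_panel_dispersions,
    make_category_comparison,
    make_strain_comparison,
    run_comparison,
)
from .simulate import (
    GroundTruth,
    PanelDesign,
    SimulationParams,
    default_design,
    generate_catalog,
    generate_counts,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report"]

log = logging.getLogger("devscreen")

FLOAT_FMT = "%.12g"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Every threshold and path the pipeline uses, in one place.

    All thresholds the screen applies are named keys here — never literals
    in stage code: ``fdr_cut`` (0.005), ``lik_cut`` (0.90), the
    deviation-curve ``flatness_epsilon``, and the A/B combine rule.
    """

    out_dir: Path = Path("devscreen_out")
    seed: int = 0
    simulation: SimulationParams = field(default_factory=SimulationParams)
    design: PanelDesign = field(default_factory=default_design)
    # input files; when set, the simulation stage is skipped
    counts_path: Path | None = None
    meta_path: Path | None = None
    catalog_path: Path | None = None
    # thresholds
    fdr_cut: float = 0.005
    lik_cut: float = 0.90
    flatness_epsilon: float = 0.05
    combine_rule: str = "all"
    # classifier controls
    n_particles: int = 100
    bootstrap_rounds: int = 3
    convergence_tol: float = 1e-5
    # stage grids
    developmental_times: tuple[float, ...] = (6.0, 12.0, 18.0)
    celltype_times: tuple[float, ...] = (12.0, 18.0)
    celltype_strains: tuple[str, ...] | None = None  # None -> all mutants
    make_plots: bool = True

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("fdr_cut", "lik_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.flatness_epsilon < 0:
            raise ConfigError("flatness_epsilon must be non-negative")
        if self.combine_rule not in ("all", "any"):
            raise ConfigError(f"combine_rule must be 'all' or 'any', got {self.combine_rule!r}")
        if self.convergence_tol <= 0:
            raise ConfigError("convergence_tol must be positive")
        given = [self.counts_path, self.meta_path, self.catalog_path]
        if any(p is not None for p in given) and not all(p is not None for p in given):
            raise ConfigError(
                "counts_path, meta_path and catalog_path must be given together"
            )

    @property
    def uses_external_data(self) -> bool:
        return self.counts_path is not None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        for k in ("counts_path", "meta_path", "catalog_path"):
            d[k] = None if d[k] is None else str(d[k])
        d["design"] = {
            "strain_ids": list(self.design.strain_ids),
            "category_of_strain": dict(self.design.category_of_strain),
            "time_points_h": list(self.design.time_points_h),
            "replicates": self.design.replicates,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = dict(raw["simulation"])
            if "length_range_nt" in sim:
                sim["length_range_nt"] = tuple(sim["length_range_nt"])
            raw["simulation"] = SimulationParams(**sim)
        if "design" in raw and isinstance(raw["design"], dict):
            d = raw["design"]
            raw["design"] = PanelDesign(
                strain_ids=tuple(d["strain_ids"]),
                category_of_strain=dict(d["category_of_strain"]),
                time_points_h=tuple(float(t) for t in d.get("time_points_h", (0, 6, 12, 18))),
                replicates=int(d.get("replicates", 2)),
            )
        for key in ("developmental_times", "celltype_times"):
            if key in raw:
                raw[key] = tuple(float(t) for t in raw[key])
        if raw.get("celltype_strains") is not None:
            raw["celltype_strains"] = tuple(raw["celltype_strains"])
        return cls(**raw)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    seed: int
    outputs: dict  # relative path -> sha256
    started_at: str
    finished_at: str
    stage_log: list

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    @property
    def out_dir(self) -> Path:
        return Path(self.config["out_dir"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


class _StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; write outputs + manifest; return the manifest."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage_log: list[dict] = []

    def record(stage: str, **info) -> None:
        log.info("stage %s: %s", stage, info)
        stage_log.append({"stage": stage, **info})

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as err:  # noqa: BLE001 - annotate with stage context
            raise _StageError(stage, err) from err

    # -- stage: input ------------------------------------------------------
    truth: GroundTruth | None = None

    def stage_input():
        nonlocal truth
        if config.uses_external_data:
            panel, catalog = read_count_panel(
                config.counts_path, config.meta_path, config.catalog_path
            )
            record("input", source="files", n_genes=panel.n_genes, n_samples=panel.n_samples)
            return panel, catalog
        params = replace(config.simulation, seed=config.seed)
        catalog, t = generate_catalog(params, config.design)
        truth = t
        panel = generate_counts(config.design, params, t, catalog)
        write_count_panel(panel, out / "counts.tsv", out / "samples.tsv")
        catalog.write_tsv(out / "catalog.tsv")
        pd.Series(sorted(t.core_gene_ids), name="gene_id").to_csv(
            out / "truth_core_genes.tsv", sep="\t", index=False
        )
        pert_rows = [
            {"gene_id": g, "strain": s, "sign": t.perturbation_sign[(g, s)]}
            for g in sorted(t.perturbed_in)
            for s in sorted(t.perturbed_in[g])
        ]
        pd.DataFrame(pert_rows, columns=["gene_id", "strain", "sign"]).to_csv(
            out / "truth_perturbations.tsv", sep="\t", index=False
        )
        _write_tsv(t.wt_profile, out / "truth_wt_profile.tsv")
        t.peak_time_h.to_frame().to_csv(
            out / "truth_peak_times.tsv", sep="\t", index_label="gene_id"
        )
        pd.Series(t.mutated_gene_of_strain, name="gene_id").to_csv(
            out / "truth_mutated_genes.tsv", sep="\t", index_label="strain"
        )
        outputs.extend(
            out / f
            for f in (
                "counts.tsv",
                "samples.tsv",
                "catalog.tsv",
                "truth_core_genes.tsv",
                "truth_perturbations.tsv",
                "truth_wt_profile.tsv",
                "truth_peak_times.tsv",
                "truth_mutated_genes.tsv",
            )
        )
        record("input", source="simulation", n_genes=panel.n_genes, n_samples=panel.n_samples)
        return panel, catalog

    panel, catalog = run_stage("input", stage_input)

    # -- stage: normalize --------------------------------------------------
    def stage_normalize():
        expr = compute_rpkm(panel, catalog)
        _write_tsv(expr.rpkm, out / "rpkm.tsv")
        outputs.append(out / "rpkm.tsv")
        record("normalize", n_genes=expr.rpkm.shape[0])
        return expr

    expr = run_stage("normalize", stage_normalize)

    # -- stage: profiles + distances + MDS ---------------------------------
    def stage_distances():
        profiles = mean_profiles(expr)
        dsets = {"concatenated": distance_matrix(profiles, "concatenated")}
        for t in profiles.time_points_h:
            dsets[f"t{int(t):02d}h"] = distance_matrix(profiles, "per_time", time_h=t)
        for name, dset in dsets.items():
            path = out / f"distances_{name}.tsv"
            _write_tsv(dset.dist, path, index_label="strain")
            outputs.append(path)
            emb = classical_mds(dset)
            mpath = out / f"mds_{name}.tsv"
            _write_tsv(emb.coords, mpath, index_label="strain")
            outputs.append(mpath)
            if config.make_plots and name == "concatenated":
                ppath = out / "mds_concatenated.png"
                _plot_mds(emb, panel, ppath)
                outputs.append(ppath)
        record("distances", n_matrices=len(dsets))
        return profiles

    profiles = run_stage("distances", stage_distances)

    # -- stage: deviation curves + timing ----------------------------------
    def stage_timing():
        wt = panel.wildtype_strain
        rows = {}
        for strain in [s for s in profiles.strain_ids if s != wt]:
            rows[strain] = deviation_curve(profiles, wt, strain).values
        curves = pd.DataFrame(rows).T
        curves.columns = [f"{t:g}h" for t in curves.columns]
        _write_tsv(curves, out / "deviation_curves.tsv", index_label="strain")
        outputs.append(out / "deviation_curves.tsv")
        if truth is not None:
            calls = timing_table(
                profiles, wt, truth.mutated_gene_of_strain, config.flatness_epsilon
            )
            _write_tsv(calls, out / "timing_calls.tsv", index_label="strain")
            outputs.append(out / "timing_calls.tsv")
            record("timing", counts=calls["category"].value_counts().to_dict())
        else:
            record("timing", counts=None)

    run_stage("timing", stage_timing)

    # -- stage: NDE classification per category/time -----------------------
    dispersions = estimate_panel_dispersions(panel)

    def stage_nde():
        tables = {}
        for i, cat in enumerate(("normal", "delayed", "no_development")):
            for j, t in enumerate(config.developmental_times):
                if not panel.samples_for(category=cat, time_h=t):
                    continue
                comp = make_category_comparison(panel, cat, t)
                tab = run_comparison(
                    panel,
                    comp,
                    n_particles=config.n_particles,
                    bootstrap_rounds=config.bootstrap_rounds,
                    convergence_tol=config.convergence_tol,
                    seed=config.seed + 100 * i + j,
                    dispersions=dispersions,
                )
                tables[(cat, t)] = tab
                path = out / f"posteriors_{comp.label}.tsv"
                _write_tsv(tab.table, path)
                outputs.append(path)
        record("nde", n_comparisons=len(tables))
        return tables

    tables = run_stage("nde", stage_nde)

    # -- stage: gene sets --------------------------------------------------
    def stage_genesets():
        result = build_gene_sets(
            tables,
            catalog,
            combine_rule=config.combine_rule,
            fdr_cut=config.fdr_cut,
            lik_cut=config.lik_cut,
            developmental_times=config.developmental_times,
        )
        _write_tsv(result.membership_table(), out / "gene_sets.tsv")
        outputs.append(out / "gene_sets.tsv")
        record("genesets", sizes=result.sizes)
        return result

    genesets = run_stage("genesets", stage_genesets)

    # -- stage: enrichment -------------------------------------------------
    def stage_enrichment():
        rows = []
        for set_name, genes in (("C", genesets.set_C), ("D", genesets.set_D)):
            for flag in ("dev_flag", "nondev_flag"):
                if not genes:
                    continue
                res = enrichment_test(genes, flag, catalog, set_name=set_name)
                rows.append(dataclasses.asdict(res))
        df = pd.DataFrame(rows)
        df.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        outputs.append(out / "enrichment.tsv")
        record("enrichment", n_tests=len(rows))

    run_stage("enrichment", stage_enrichment)

    # -- stage: cell-type panel --------------------------------------------
    def stage_celltype():
        ct_panel = catalog.celltype_panel
        strains = config.celltype_strains
        if strains is None:
            wt = panel.wildtype_strain
            strains = tuple(
                s for s in dict.fromkeys(panel.samples["strain"]) if s != wt
            )
        rows = []
        for i, strain in enumerate(strains):
            tbt = {}
            for j, t in enumerate(config.celltype_times):
                comp = make_strain_comparison(panel, strain, t)
                tbt[t] = run_comparison(
                    panel,
                    comp,
                    n_particles=config.n_particles,
                    bootstrap_rounds=config.bootstrap_rounds,
                    convergence_tol=config.convergence_tol,
                    seed=config.seed + 10000 + 10 * i + j,
                    dispersions=dispersions,
                )
            res = celltype_alteration_fraction(
                strain, ct_panel, tbt, config.fdr_cut, config.lik_cut
            )
            rows.append(dataclasses.asdict(res))
        df = pd.DataFrame(rows)
        df.to_csv(
            out / "celltype_fractions.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        outputs.append(out / "celltype_fractions.tsv")
        record("celltype", n_strains=len(rows))

    if catalog.celltype_panel:
        run_stage("celltype", stage_celltype)

    # -- stage: recovery vs ground truth -----------------------------------
    def stage_recovery():
        if truth is None or not truth.core_gene_ids:
            return
        core = truth.core_gene_ids
        d = genesets.set_D
        tp = len(d & core)
        precision = tp / len(d) if d else float("nan")
        recall = tp / len(core)
        rec = pd.DataFrame(
            [
                {
                    "set": "D",
                    "n_set": len(d),
                    "n_core": len(core),
                    "true_positives": tp,
                    "precision": precision,
                    "recall": recall,
                }
            ]
        )
        rec.to_csv(out / "recovery.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        outputs.append(out / "recovery.tsv")
        record("recovery", precision=precision, recall=recall)

    run_stage("recovery", stage_recovery)

    finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        outputs={str(p.relative_to(out)): _sha256(p) for p in outputs},
        started_at=started,
        finished_at=finished,
        stage_log=stage_log,
    )

    # -- stage: report -----------------------------------------------------
    text = report(manifest)
    (out / "report.md").write_text(text)
    manifest.outputs["report.md"] = _sha256(out / "report.md")
    manifest.to_json(out / "manifest.json")
    return manifest


def _plot_mds(emb, panel: CountPanel, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cat_of = dict(zip(panel.samples["strain"], panel.samples["category"]))
    colors = {
        "wildtype": "tab:green",
        "normal": "tab:blue",
        "delayed": "tab:orange",
        "no_development": "tab:red",
    }
    fig, ax = plt.subplots(figsize=(6, 5))
    for strain, (x, y) in emb.coords.iterrows():
        c = colors.get(cat_of.get(strain, "normal"), "gray")
        ax.scatter(x, y, c=c, s=40)
        ax.annotate(strain, (x, y), fontsize=6, ha="center", va="bottom")
    ax.set_xlabel("MDS 1 (dimensionless)")
    ax.set_ylabel("MDS 2 (dimensionless)")
    ax.set_title("Transcriptional phenotypes (concatenated time course)")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Date": None})
    plt.close(fig)


def report(manifest: RunManifest) -> str:
    """Human-readable markdown summary built from a finished run's outputs."""
    out = manifest.out_dir
    lines = [
        "# devscreen run report",
        "",
        f"- version: {manifest.version}",
        f"- seed: {manifest.seed}",
        "",
    ]
    gs = out / "gene_sets.tsv"
    if gs.exists():
        mem = pd.read_csv(gs, sep="\t", index_col="gene_id")
        lines += [
            "## Gene sets",
            "",
            "| set | size | meaning |",
            "|---|---|---|",
            f"| A | {int(mem['in_A'].sum())} | unperturbed in normal developers |",
            f"| B | {int(mem['in_B'].sum())} | unperturbed in delayed / non-developers |",
            f"| C | {int(mem['in_C'].sum())} | A \\ B |",
            f"| D | {int(mem['in_D'].sum())} | C ∩ conserved orthologs |",
            "",
        ]
    enr = out / "enrichment.tsv"
    if enr.exists():
        df = pd.read_csv(enr, sep="\t")
        lines += ["## Label enrichment", ""]
        lines.append("| set | label | % in set | % background | p (one-sided) |")
        lines.append("|---|---|---|---|---|")
        for _, r in df.iterrows():
            lines.append(
                f"| {r['set_name']} | {r['label_name']} | {r['percent_in_set']:.1f} "
                f"| {r['percent_background']:.1f} | {r['p_value']:.3g} |"
            )
        lines.append("")
    tc = out / "timing_calls.tsv"
    if tc.exists():
        calls = pd.read_csv(tc, sep="\t")
        counts = calls["category"].value_counts()
        lines += [
            "## Peak abundance vs maximal deviation",
            "",
            "| Precedes | Equals | Succeeds | No correlation |",
            "|---|---|---|---|",
            "| {} | {} | {} | {} |".format(
                *(int(counts.get(c, 0)) for c in ("precedes", "equals", "succeeds", "no_correlation"))
            ),
            "",
        ]
    ct = out / "celltype_fractions.tsv"
    if ct.exists():
        df = pd.read_csv(ct, sep="\t")
        top = df.sort_values("fraction_altered", ascending=False).head(5)
        lines += ["## Cell-type panel alteration (top strains)", ""]
        lines.append("| strain | panel | altered | fraction |")
        lines.append("|---|---|---|---|")
        for _, r in top.iterrows():
            lines.append(
                f"| {r['strain_id']} | {int(r['panel_size'])} | {int(r['n_altered'])} "
                f"| {r['fraction_altered']:.2f} |"
            )
        lines.append("")
    rec = out / "recovery.tsv"
    if rec.exists():
        df = pd.read_csv(rec, sep="\t")
        r = df.iloc[0]
        lines += [
            "## Planted-core recovery (simulation only)",
            "",
            f"Set D recovered {int(r['true_positives'])} of {int(r['n_core'])} planted "
            f"core genes: precision {r['precision']:.3f}, recall {r['recall']:.3f}.",
            "",
        ]
    return "\n".join(lines)
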