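"""Synthetic mutant-panel generator with planted ground truth.

Emulates the statistical structure of a developmental RNA-seq screen in a
social amoeba: a wild-type strain plus a panel of mutant strains sampled
over a developmental time course (default 0/6/12/18 h, two replicates),
with negative-binomial read counts. Mutants fall into three phenotype
categories — normal development, delayed development, and no development.

Planted structure, recorded in :class:`GroundTruth` so every downstream
stage can be scored against it:

* a *core* set of developmentally regulated genes whose expression is
  untouched in normally developing mutants but perturbed in the delayed /
  non-developing strains (both by their shifted or arrested temporal
  programme and by explicit fold changes);
* *perturbable* background genes hit by planted fold changes in a random
  subset of the normally developing mutants;
* annotation labels (developmental, non-developmental, conserved-ortholog,
  cell-type enrichment) with controllable enrichment of developmental
  labels inside the core set.

Two independent random streams are used: one for labels/ground truth and
one for count noise, so redrawing counts never changes gene memberships.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountPanel, GeneCatalog

__all__ = [
    "PanelDesign",
    "SimulationParams",
    "GroundTruth",
    "default_design",
    "generate_catalog",
    "generate_counts",
    "simulate_panel",
    "calibration_panel",
    "expected_mean_matrix",
]

CATEGORIES = ("wildtype", "normal", "delayed", "no_development")


class DesignError(ValueError):
    """Raised for inconsistent panel designs or simulation parameters."""


@dataclass(frozen=True)
class PanelDesign:
    """Which strains exist, their phenotype category, and the sampling grid."""

    strain_ids: tuple[str, ...]
    category_of_strain: Mapping[str, str]
    time_points_h: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    replicates: int = 2

    def __post_init__(self) -> None:
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise DesignError("duplicate strain ids")
        for s in self.strain_ids:
            if s not in self.category_of_strain:
                raise DesignError(f"strain {s!r} has no category")
            if self.category_of_strain[s] not in CATEGORIES:
                raise DesignError(
                    f"unknown category {self.category_of_strain[s]!r} for strain {s!r}"
                )
        n_wt = sum(
            1 for s in self.strain_ids if self.category_of_strain[s] == "wildtype"
        )
        if n_wt != 1:
            raise DesignError(f"expected exactly one wildtype strain, found {n_wt}")
        times = self.time_points_h
        if any(t < 0 for t in times):
            raise DesignError("time points must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DesignError("time points must be strictly increasing")
        if self.replicates < 1:
            raise DesignError("replicates must be a positive integer")

    @property
    def wildtype(self) -> str:
        return next(
            s for s in self.strain_ids if self.category_of_strain[s] == "wildtype"
        )

    @property
    def mutants(self) -> tuple[str, ...]:
        return tuple(s for s in self.strain_ids if s != self.wildtype)

    def strains_in_category(self, category: str) -> tuple[str, ...]:
        return tuple(
            s for s in self.strain_ids if self.category_of_strain[s] == category
        )


def default_design(
    n_normal: int = 30,
    n_delayed: int = 4,
    n_no_development: int = 1,
    time_points_h: Sequence[float] = (0.0, 6.0, 12.0, 18.0),
    replicates: int = 2,
) -> PanelDesign:
    """Wild type plus 35 mutants: 30 normal, 4 delayed, 1 non-developing.

    The split mirrors a typical transporter-mutant panel in which most
    knockouts develop normally, a few are delayed in forming tipped
    aggregates, and one fails to develop.
    """
    strains = ["WT"]
    cats = {"WT": "wildtype"}
    for i in range(n_normal):
        s = f"N{i + 1:02d}"
        strains.append(s)
        cats[s] = "normal"
    for i in range(n_delayed):
        s = f"D{i + 1:02d}"
        strains.append(s)
        cats[s] = "delayed"
    for i in range(n_no_development):
        s = f"X{i + 1:02d}"
        strains.append(s)
        cats[s] = "no_development"
    return PanelDesign(
        strain_ids=tuple(strains),
        category_of_strain=cats,
        time_points_h=tuple(float(t) for t in time_points_h),
        replicates=replicates,
    )


@dataclass(frozen=True)
class SimulationParams:
    """Tunable knobs of the generative model.

    Counts are negative binomial with variance ``mu + mu**2 / nb_dispersion``
    (``nb_dispersion`` is the NB size; large values approach Poisson).
    ``effect_size_logfc`` is the magnitude of planted perturbations on the
    natural-log scale. ``enrichment_of_dev_labels_in_core`` multiplies the
    background odds of carrying a developmental label for core genes.
    """

    n_genes: int = 5000
    frac_core: float = 0.10
    frac_perturbable: float = 0.30
    nb_dispersion: float = 10.0
    library_size_mean: float = 1e6
    library_size_cv: float = 0.1
    effect_size_logfc: float = 1.5
    enrichment_of_dev_labels_in_core: float = 3.0
    seed: int = 0
    # label frequencies (genome background)
    frac_dev_labels: float = 0.08
    frac_nondev_labels: float = 0.05
    frac_conserved: float = 0.30
    conserved_rate_in_core: float = 0.95
    frac_celltype: float = 0.108
    # temporal programme
    core_amplitude: float = 2.0
    background_amplitude: float = 0.4
    frac_dynamic_background: float = 0.4
    # perturbation placement
    perturbed_strain_rate: float = 0.1
    delay_shift_points: int = 1
    length_range_nt: tuple[int, int] = (300, 8000)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise DesignError("n_genes must be positive")
        for name in (
            "nb_dispersion",
            "library_size_mean",
            "library_size_cv",
            "effect_size_logfc",
            "core_amplitude",
        ):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be non-negative")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise DesignError("nb_dispersion and library_size_mean must be positive")
        for name in (
            "frac_core",
            "frac_perturbable",
            "frac_dev_labels",
            "frac_nondev_labels",
            "frac_conserved",
            "conserved_rate_in_core",
            "frac_celltype",
            "frac_dynamic_background",
            "perturbed_strain_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name} must be in [0, 1], got {v}")
        if self.frac_core + self.frac_perturbable > 1.0 + 1e-12:
            raise DesignError("frac_core + frac_perturbable must be <= 1")
        if self.enrichment_of_dev_labels_in_core < 1.0:
            raise DesignError("enrichment_of_dev_labels_in_core must be >= 1")
        lo, hi = self.length_range_nt
        if lo <= 0 or hi < lo:
            raise DesignError("length_range_nt must be a positive range")


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring downstream inference."""

    core_gene_ids: frozenset
    perturbed_in: dict  # gene_id -> frozenset of strain ids
    perturbation_sign: dict  # (gene_id, strain_id) -> +1 / -1
    wt_profile: pd.DataFrame  # genes x time points, expected relative abundance
    peak_time_h: pd.Series  # gene -> hour of the wild-type abundance peak
    mutated_gene_of_strain: dict  # mutant strain -> the gene it "knocks out"

    def __post_init__(self) -> None:
        argmax_t = self.wt_profile.idxmax(axis=1).astype(float)
        if not (argmax_t == self.peak_time_h.astype(float)).all():
            raise DesignError("peak_time_h does not match the wt_profile argmax")

    def perturbed_genes_of(self, strain: str) -> frozenset:
        return frozenset(
            g for g, strains in self.perturbed_in.items() if strain in strains
        )


def _label_rng(params: SimulationParams) -> np.random.Generator:
    return np.random.default_rng([params.seed, 11])


def _count_rng(params: SimulationParams) -> np.random.Generator:
    return np.random.default_rng([params.seed, 22])


def generate_catalog(
    params: SimulationParams, design: PanelDesign | None = None
) -> tuple[GeneCatalog, GroundTruth]:
    """Draw gene annotations, wild-type temporal profiles, and planted effects.

    Core genes are developmentally regulated (large temporal amplitude) and
    are perturbed in every delayed / non-developing strain; perturbable
    background genes are perturbed in a random subset of the normally
    developing strains (at least one each). Developmental labels are planted
    so that their odds inside the core set are
    ``enrichment_of_dev_labels_in_core`` times the background odds, and the
    conserved-ortholog flag is a superset biased toward core genes.
    """
    if design is None:
        design = default_design()
    rng = _label_rng(params)
    n = params.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
    times = np.asarray(design.time_points_h, dtype=float)
    n_t = len(times)

    lo, hi = params.length_range_nt
    lengths = rng.integers(lo, hi + 1, size=n)

    n_core = round(params.frac_core * n)
    n_pert = round(params.frac_perturbable * n)
    order = rng.permutation(n)
    core_idx = np.sort(order[:n_core])
    pert_idx = np.sort(order[n_core : n_core + n_pert])
    is_core = np.zeros(n, dtype=bool)
    is_core[core_idx] = True

    # labels ---------------------------------------------------------------
    bg_odds = params.frac_dev_labels / (1.0 - params.frac_dev_labels)
    core_odds = params.enrichment_of_dev_labels_in_core * bg_odds
    p_dev = np.where(is_core, core_odds / (1.0 + core_odds), params.frac_dev_labels)
    dev_flag = rng.random(n) < p_dev
    nondev_flag = (~dev_flag) & (rng.random(n) < params.frac_nondev_labels)

    if n_core > 0:
        p_cons_bg = (params.frac_conserved * n - params.conserved_rate_in_core * n_core) / max(
            n - n_core, 1
        )
    else:
        p_cons_bg = params.frac_conserved
    p_cons_bg = float(np.clip(p_cons_bg, 0.0, 1.0))
    p_cons = np.where(is_core, params.conserved_rate_in_core, p_cons_bg)
    conserved_flag = rng.random(n) < p_cons

    celltype = np.array(["none"] * n, dtype=object)
    n_ct = round(params.frac_celltype * n)
    ct_idx = rng.choice(n, size=n_ct, replace=False)
    half = n_ct // 2
    celltype[ct_idx[:half]] = "prespore"
    celltype[ct_idx[half:]] = "prestalk"

    # wild-type temporal programme ----------------------------------------
    base = rng.lognormal(mean=math.log(30.0), sigma=1.2, size=n)
    peak_idx = rng.integers(0, n_t, size=n)
    amp = np.zeros(n)
    amp[is_core] = params.core_amplitude * rng.uniform(0.75, 1.25, size=n_core)
    dyn_bg = (~is_core) & (rng.random(n) < params.frac_dynamic_background)
    amp[dyn_bg] = rng.exponential(params.background_amplitude, size=int(dyn_bg.sum()))
    # tent-shaped log profile peaking at the planted time
    dist = np.abs(np.arange(n_t)[None, :] - peak_idx[:, None])
    shape = 1.0 - dist / max(n_t - 1, 1)
    log_prof = np.log(base)[:, None] + amp[:, None] * shape
    wt_profile = pd.DataFrame(np.exp(log_prof), index=genes, columns=times)
    peak_time = pd.Series(
        np.where(amp > 0, times[peak_idx], times[0]), index=genes, name="peak_time_h"
    )

    # planted perturbations ------------------------------------------------
    normal_strains = design.strains_in_category("normal")
    affected_strains = design.strains_in_category("delayed") + design.strains_in_category(
        "no_development"
    )
    # Perturbation direction is a property of the gene, shared by every
    # strain that perturbs it: dysregulation of a transcript downstream of
    # related lesions has a characteristic direction, and the pooled
    # category-versus-wild-type contrast the screen relies on assumes the
    # category mean moves.
    perturbed_in: dict = {}
    signs: dict = {}
    if n_pert and normal_strains:
        hit = rng.random((n_pert, len(normal_strains))) < params.perturbed_strain_rate
        none_hit = ~hit.any(axis=1)
        if none_hit.any():
            forced = rng.integers(0, len(normal_strains), size=int(none_hit.sum()))
            hit[np.flatnonzero(none_hit), forced] = True
        for row, gi in enumerate(pert_idx):
            g = genes[gi]
            strains = frozenset(
                normal_strains[j] for j in np.flatnonzero(hit[row])
            )
            perturbed_in[g] = strains
            sign = 1 if rng.random() < 0.5 else -1
            for s in sorted(strains):
                signs[(g, s)] = sign
    for gi in core_idx:
        g = genes[gi]
        perturbed_in[g] = frozenset(affected_strains)
        sign = 1 if rng.random() < 0.5 else -1
        for s in sorted(affected_strains):
            signs[(g, s)] = sign

    # each mutant "knocks out" one developmentally regulated gene
    dynamic_pool = np.flatnonzero(amp > 0)
    mutants = design.mutants
    if len(dynamic_pool) >= len(mutants):
        chosen = rng.choice(dynamic_pool, size=len(mutants), replace=False)
    else:  # degenerate tiny panels: allow any gene
        chosen = rng.choice(n, size=len(mutants), replace=False)
    mutated_gene = {s: genes[gi] for s, gi in zip(mutants, chosen)}

    catalog = GeneCatalog(
        pd.DataFrame(
            {
                "mappable_exon_length_nt": lengths,
                "dev_flag": dev_flag,
                "nondev_flag": nondev_flag,
                "conserved_flag": conserved_flag,
                "celltype_label": celltype,
            },
            index=genes,
        )
    )
    truth = GroundTruth(
        core_gene_ids=frozenset(genes[core_idx]),
        perturbed_in=perturbed_in,
        perturbation_sign=signs,
        wt_profile=wt_profile,
        peak_time_h=peak_time,
        mutated_gene_of_strain=mutated_gene,
    )
    return catalog, truth


def _source_time_index(category: str, t_idx: int, shift: int) -> int:
    if category == "delayed":
        return max(t_idx - shift, 0)
    if category == "no_development":
        return 0
    return t_idx


def expected_mean_matrix(
    design: PanelDesign,
    params: SimulationParams,
    truth: GroundTruth,
    catalog: GeneCatalog | None = None,
) -> pd.DataFrame:
    """Expected counts per (gene, strain x time) for a unit library.

    Columns are (strain, time_h) and each sums to one: sequencing depth
    is fixed, so counts are compositional. Unperturbed genes in normally
    developing strains keep exactly the wild-type relative abundance (up
    to the strain's composition scalar, absorbed downstream by library
    factors) — the planted no-differential-expression structure.
    """
    times = list(design.time_points_h)
    prof = truth.wt_profile.to_numpy(dtype=float)
    genes = truth.wt_profile.index
    if catalog is not None:
        weight = catalog.lengths_nt.reindex(genes).to_numpy(dtype=float) / 1e3
    else:
        weight = np.ones(len(genes))
    rel_wt = prof * weight[:, None]

    pert_mult: dict[str, np.ndarray] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for strain in design.strain_ids:
        mult = np.ones(len(genes))
        for g, strains in truth.perturbed_in.items():
            if strain in strains:
                sgn = truth.perturbation_sign[(g, strain)]
                mult[gene_pos[g]] = math.exp(sgn * params.effect_size_logfc)
        pert_mult[strain] = mult

    cols = {}
    for strain in design.strain_ids:
        cat = design.category_of_strain[strain]
        for t_idx, t in enumerate(times):
            src = _source_time_index(cat, t_idx, params.delay_shift_points)
            rel = rel_wt[:, src] * pert_mult[strain]
            cols[(strain, t)] = rel / rel.sum()
    out = pd.DataFrame(cols, index=genes)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["strain", "time_h"])
    return out


def generate_counts(
    design: PanelDesign,
    params: SimulationParams,
    truth: GroundTruth,
    catalog: GeneCatalog | None = None,
    count_seed: int | None = None,
) -> CountPanel:
    """Draw the negative-binomial count matrix for the whole panel.

    Sample library sizes are log-normal with mean ``library_size_mean`` and
    CV ``library_size_cv``. Byte-identical output for a fixed seed. When a
    catalog is given, expected counts scale with mappable exon length, so
    RPKM recovers the planted abundance programme. ``count_seed`` redraws
    the count noise stream without touching the label stream, so ground
    truth stays fixed across redraws.
    """
    if set(truth.wt_profile.columns) != set(design.time_points_h):
        raise DesignError("ground-truth profile time grid does not match the design")
    if count_seed is None:
        rng = _count_rng(params)
    else:
        rng = np.random.default_rng([count_seed, 22])
    mean_rel = expected_mean_matrix(design, params, truth, catalog)
    genes = mean_rel.index
    size = params.nb_dispersion

    cv = params.library_size_cv
    sigma2 = math.log(1.0 + cv**2)
    mu_log = math.log(params.library_size_mean) - sigma2 / 2.0

    sample_ids = []
    meta_rows = []
    count_cols = []
    for strain in design.strain_ids:
        cat = design.category_of_strain[strain]
        for t in design.time_points_h:
            rel = mean_rel[(strain, t)].to_numpy()
            for rep in range(1, design.replicates + 1):
                sid = f"{strain}_{int(t):02d}h_r{rep}"
                lib = rng.lognormal(mean=mu_log, sigma=math.sqrt(sigma2))
                mu = rel * lib
                p = size / (size + np.maximum(mu, 1e-300))
                counts = np.where(mu > 0, rng.negative_binomial(size, p), 0)
                sample_ids.append(sid)
                meta_rows.append(
                    {"strain": strain, "category": cat, "time_h": t, "replicate": rep}
                )
                count_cols.append(counts.astype(np.int64))
    counts = pd.DataFrame(
        np.column_stack(count_cols), index=genes, columns=sample_ids
    )
    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    return CountPanel(counts=counts, samples=samples)


def simulate_panel(
    params: SimulationParams | None = None, design: PanelDesign | None = None
) -> tuple[CountPanel, GeneCatalog, GroundTruth]:
    """Catalog + counts in one call with the default panel design."""
    if params is None:
        params = SimulationParams()
    if design is None:
        design = default_design()
    catalog, truth = generate_catalog(params, design)
    panel = generate_counts(design, params, truth, catalog)
    return panel, catalog, truth


def calibration_panel(
    n_genes: int = 5000,
    de_fraction: float = 0.1,
    effect_size_logfc: float = 1.5,
    replicates: int = 2,
    seed: int = 0,
) -> tuple[CountPanel, GeneCatalog, GroundTruth]:
    """Two-condition panel for error-rate calibration of the NDE classifier.

    Wild type plus a single normally developing mutant in which exactly
    ``de_fraction`` of the genes carry a planted fold change; all other
    genes are exchangeable with wild type. The planted set is
    ``truth.perturbed_genes_of('N01')``.
    """
    design = PanelDesign(
        strain_ids=("WT", "N01"),
        category_of_strain={"WT": "wildtype", "N01": "normal"},
        replicates=replicates,
    )
    params = SimulationParams(
        n_genes=n_genes,
        frac_core=0.0,
        frac_perturbable=de_fraction,
        effect_size_logfc=effect_size_logfc,
        perturbed_strain_rate=1.0,
        seed=seed,
    )
    catalog, truth = generate_catalog(params, design)
    panel = generate_counts(design, params, truth, catalog)
    return panel, catalog, truth
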