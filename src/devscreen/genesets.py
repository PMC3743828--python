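"""Gene-set algebra on NDE calls, enrichment tests, and cell-type panel fractions.

The screen's central idea: genes whose expression is *unperturbed* in
mutants that develop normally, but *not* unperturbed in mutants whose
development is delayed or absent, are candidates for developmental
importance. Concretely:

* **Set A** — genes classified NDE in the normal-development category at
  every developmental time point (the combine rule is configurable);
* **Set B** — genes NDE in the delayed-development group *or* in the
  no-development group (union of the two A-style sets);
* **Set C = A \\ B** — unperturbed exclusively in normal developers;
* **Set D = C ∩ conserved** — the subset whose expression programme is
  conserved across species (the catalog's ortholog-conservation flag).

Validation is by label enrichment: a one-sided hypergeometric test of the
developmental (or non-developmental) annotation inside a set against the
genome background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneCatalog
from .nde import PosteriorTable, classify_de, classify_nde

__all__ = [
    "GeneSetResult",
    "EnrichmentResult",
    "CellTypePanelResult",
    "combine_nde_calls",
    "build_set_A",
    "build_set_B",
    "derive_set_C",
    "derive_set_D",
    "build_gene_sets",
    "enrichment_test",
    "celltype_alteration_fraction",
]

CombineRule = Literal["all", "any"]


def combine_nde_calls(
    calls_by_time: Mapping[float, frozenset], combine_rule: CombineRule = "all"
) -> frozenset:
    """Intersect ("all") or union ("any") NDE calls across time points."""
    if not calls_by_time:
        return frozenset()
    sets = [frozenset(s) for s in calls_by_time.values()]
    if combine_rule == "all":
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out
    if combine_rule == "any":
        return frozenset().union(*sets)
    raise ValueError(f"unknown combine rule {combine_rule!r}")


def build_set_A(
    normal_calls_by_time: Mapping[float, frozenset],
    combine_rule: CombineRule = "all",
    expected_times: Iterable[float] = (6.0, 12.0, 18.0),
) -> frozenset:
    """Genes unperturbed in the normal-development category.

    Requires NDE calls at every expected developmental time point (the
    0-h growth point is not part of the screen).
    """
    missing = set(float(t) for t in expected_times) - set(
        float(t) for t in normal_calls_by_time
    )
    if missing:
        raise ValueError(f"missing NDE calls at time points: {sorted(missing)}")
    return combine_nde_calls(normal_calls_by_time, combine_rule)


def build_set_B(
    delayed_calls_by_time: Mapping[float, frozenset],
    no_development_calls_by_time: Mapping[float, frozenset],
    combine_rule: CombineRule = "all",
    expected_times: Iterable[float] = (6.0, 12.0, 18.0),
) -> frozenset:
    """Genes unperturbed in the delayed *or* the no-development group (union)."""
    b_del = build_set_A(delayed_calls_by_time, combine_rule, expected_times)
    b_nod = build_set_A(no_development_calls_by_time, combine_rule, expected_times)
    return b_del | b_nod


def derive_set_C(set_a: frozenset, set_b: frozenset) -> frozenset:
    """Set difference A \\ B: unperturbed exclusively in normal developers."""
    return frozenset(set_a) - frozenset(set_b)


def derive_set_D(set_c: frozenset, catalog: GeneCatalog) -> frozenset:
    """Intersection of set C with the conserved-expression ortholog flag."""
    return frozenset(set_c) & catalog.genes_with_flag("conserved_flag")


@dataclass
class GeneSetResult:
    """Sets A-D with the per-gene NDE evidence they were derived from."""

    set_A: frozenset
    set_B: frozenset
    set_C: frozenset
    set_D: frozenset
    combine_rule: str
    fdr_cut: float
    lik_cut: float
    evidence: pd.DataFrame  # per-gene likelihood/FDR columns per category/time

    def __post_init__(self) -> None:
        if self.set_C & self.set_B:
            raise ValueError("set C must be disjoint from set B")
        if not self.set_C <= self.set_A:
            raise ValueError("set C must be a subset of set A")
        if not self.set_D <= self.set_C:
            raise ValueError("set D must be a subset of set C")

    @property
    def sizes(self) -> dict:
        return {
            "A": len(self.set_A),
            "B": len(self.set_B),
            "C": len(self.set_C),
            "D": len(self.set_D),
        }

    def membership_table(self) -> pd.DataFrame:
        idx = self.evidence.index
        out = pd.DataFrame(
            {
                "in_A": idx.isin(list(self.set_A)),
                "in_B": idx.isin(list(self.set_B)),
                "in_C": idx.isin(list(self.set_C)),
                "in_D": idx.isin(list(self.set_D)),
            },
            index=idx,
        )
        return pd.concat([out, self.evidence], axis=1)


_CATEGORY_CODE = {"normal": "reg", "delayed": "del", "no_development": "nod"}


def build_gene_sets(
    tables: Mapping[tuple[str, float], PosteriorTable],
    catalog: GeneCatalog,
    combine_rule: CombineRule = "all",
    fdr_cut: float = 0.005,
    lik_cut: float = 0.90,
    developmental_times: Iterable[float] = (6.0, 12.0, 18.0),
) -> GeneSetResult:
    """Full A/B/C/D derivation from per-(category, time) posterior tables.

    ``tables`` must cover the three mutant categories at every
    developmental time point. The evidence table carries likelihood and
    FDR columns named by category code and time, e.g. ``Lik.NDEreg06hr``.
    """
    times = [float(t) for t in developmental_times]
    calls: dict[str, dict[float, frozenset]] = {}
    for cat in ("normal", "delayed", "no_development"):
        calls[cat] = {}
        for t in times:
            if (cat, t) not in tables:
                raise ValueError(f"missing posterior table for ({cat!r}, {t} h)")
            calls[cat][t] = classify_nde(tables[(cat, t)], fdr_cut, lik_cut)

    set_a = build_set_A(calls["normal"], combine_rule, times)
    set_b = build_set_B(calls["delayed"], calls["no_development"], combine_rule, times)
    set_c = derive_set_C(set_a, set_b)
    set_d = derive_set_D(set_c, catalog)

    cols = {}
    for (cat, t), tab in sorted(tables.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        code = _CATEGORY_CODE.get(cat, cat)
        cols[f"Lik.NDE{code}{int(t):02d}hr"] = tab.table["likelihood_NDE"]
        cols[f"FDR.NDE{code}{int(t):02d}hr"] = tab.table["fdr_NDE"]
    evidence = pd.DataFrame(cols)

    return GeneSetResult(
        set_A=set_a,
        set_B=set_b,
        set_C=set_c,
        set_D=set_d,
        combine_rule=combine_rule,
        fdr_cut=fdr_cut,
        lik_cut=lik_cut,
        evidence=evidence,
    )


@dataclass
class EnrichmentResult:
    """One-sided hypergeometric enrichment of a label inside a gene set."""

    set_name: str
    label_name: str
    k: int  # labeled genes in the set
    n: int  # set size
    K: int  # labeled genes genome-wide
    N: int  # genome size
    percent_in_set: float
    percent_background: float
    odds_ratio: float
    p_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("labeled count exceeds set or background label count")


def enrichment_test(
    gene_set: Iterable[str],
    label_flag: str,
    catalog: GeneCatalog,
    set_name: str = "",
    alternative: Literal["greater", "two-sided"] = "greater",
) -> EnrichmentResult:
    """Hypergeometric test of label over-representation in a gene set.

    ``label_flag`` names a boolean catalog column (``dev_flag``,
    ``nondev_flag``, ``conserved_flag``). The one-sided upper-tail
    p-value is P[X >= k] for X ~ Hypergeom(N, K, n).
    """
    genes = frozenset(gene_set)
    if not genes <= frozenset(catalog.gene_ids):
        stray = sorted(genes - frozenset(catalog.gene_ids))[:5]
        raise ValueError(f"gene set contains genes absent from the catalog: {stray}")
    N = catalog.n_genes
    if N == 0:
        raise ValueError("empty catalog")
    labeled = catalog.genes_with_flag(label_flag)
    K = len(labeled)
    n = len(genes)
    k = len(genes & labeled)
    p_upper = float(hypergeom.sf(k - 1, N, K, n))
    if alternative == "greater":
        p = p_upper
    else:
        p_lower = float(hypergeom.cdf(k, N, K, n))
        p = min(1.0, 2.0 * min(p_upper, p_lower))
    a, b = k, n - k
    c, d = K - k, N - K - (n - k)
    if b == 0 or c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        set_name=set_name,
        label_name=label_flag,
        k=k,
        n=n,
        K=K,
        N=N,
        percent_in_set=100.0 * k / n if n else float("nan"),
        percent_background=100.0 * K / N,
        odds_ratio=float(odds),
        p_value=p,
    )


@dataclass
class CellTypePanelResult:
    """How much of the cell-type enriched transcript panel a mutant alters."""

    strain_id: str
    panel_size: int
    n_altered: int
    fraction_altered: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_altered <= self.panel_size:
            raise ValueError("altered count outside [0, panel size]")


def celltype_alteration_fraction(
    strain_id: str,
    panel_genes: Iterable[str],
    tables_by_time: Mapping[float, PosteriorTable],
    fdr_cut: float = 0.005,
    lik_cut: float = 0.90,
) -> CellTypePanelResult:
    """Fraction of a cell-type panel differentially abundant in one mutant.

    A gene counts as altered if it meets the DE criteria (FDR below cut,
    likelihood above cut) at *either* assessed time point (the default
    pipeline uses 12 h and 18 h).
    """
    panel = frozenset(panel_genes)
    if not panel:
        raise ValueError("empty cell-type panel")
    if not tables_by_time:
        raise ValueError("no posterior tables supplied")
    altered: frozenset = frozenset()
    for t, tab in tables_by_time.items():
        altered |= classify_de(tab, fdr_cut, lik_cut) & panel
    return CellTypePanelResult(
        strain_id=strain_id,
        panel_size=len(panel),
        n_altered=len(altered),
        fraction_altered=len(altered) / len(panel),
    )
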