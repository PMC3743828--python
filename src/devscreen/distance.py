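"""Transcriptional-phenotype distances, classical MDS, and timing analysis.

A strain's genome-wide expression profile is treated as a quantitative
phenotype. The distance between two strains is ``1 - rho`` where ``rho``
is Spearman's rank correlation between their mean expression vectors —
either the per-time-point vectors or, in *concatenated* mode, the vectors
of all time points joined end to end. Distances live in [0, 2].

The embedding is classical (Torgerson) metric MDS: deterministic, exact
for Euclidean distance matrices, and adequate for the qualitative
configuration plots this analysis needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import StrainProfileSet

__all__ = [
    "StrainDistanceSet",
    "MdsEmbedding",
    "DeviationCurve",
    "TimingCall",
    "spearman_distance",
    "distance_matrix",
    "classical_mds",
    "deviation_curve",
    "timing_category",
    "timing_table",
]

TIMING_CATEGORIES = ("precedes", "equals", "succeeds", "no_correlation")


class ConstantProfileError(ValueError):
    """A profile with zero rank variance has no defined rank correlation."""


def spearman_distance(x: np.ndarray, y: np.ndarray) -> float:
    """``1 - rho_Spearman`` with average ranks for ties.

    Raises :class:`ConstantProfileError` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        raise ConstantProfileError("constant vector has undefined rank correlation")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return 1.0 - rho


@dataclass
class StrainDistanceSet:
    """Symmetric strain x strain distance matrix with its mode of computation."""

    mode: str  # "concatenated" or "per_time"
    time_h: float | None
    dist: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.dist.to_numpy()
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if d.min() < -1e-12 or d.max() > 2.0 + 1e-12:
            raise ValueError("rank-correlation distances must lie in [0, 2]")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.dist.index)


def distance_matrix(
    profiles: StrainProfileSet,
    mode: Literal["concatenated", "per_time"] = "concatenated",
    time_h: float | None = None,
) -> StrainDistanceSet:
    """All pairwise strain distances.

    In concatenated mode each strain is represented by its per-time mean
    vectors joined over the full time course before ranking; in per_time
    mode by the single vector at ``time_h``.
    """
    strains = profiles.strain_ids
    if len(strains) < 2:
        raise ValueError("need at least two strains")
    if mode == "concatenated":
        vectors = {s: profiles.concatenated(s) for s in strains}
    elif mode == "per_time":
        if time_h is None:
            raise ValueError("per_time mode requires time_h")
        vectors = {s: profiles.vector(s, float(time_h)) for s in strains}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ranks = {}
    for s, v in vectors.items():
        r = rankdata(v)
        if r.std() == 0:
            raise ConstantProfileError(f"strain {s!r} has a constant profile")
        ranks[s] = (r - r.mean()) / r.std()

    n = len(strains)
    d = np.zeros((n, n))
    for i, a in enumerate(strains):
        for j in range(i + 1, n):
            rho = float(np.mean(ranks[a] * ranks[strains[j]]))
            d[i, j] = d[j, i] = 1.0 - rho
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return StrainDistanceSet(
        mode=mode,
        time_h=None if mode == "concatenated" else float(time_h),
        dist=pd.DataFrame(d, index=strains, columns=strains),
    )


@dataclass
class MdsEmbedding:
    """2-D configuration recovered from a distance matrix; axes dimensionless."""

    coords: pd.DataFrame  # strains x (x, y)
    stress: float
    eigenvalues: np.ndarray

    @property
    def strain_ids(self) -> list[str]:
        return list(self.coords.index)


def classical_mds(dist: StrainDistanceSet | pd.DataFrame) -> MdsEmbedding:
    """Torgerson MDS: double-centred squared distances, top-2 eigenpairs.

    Accepts a :class:`StrainDistanceSet` or any square symmetric distance
    DataFrame. The orientation is made deterministic by flipping each
    axis so the first strain with a nonzero coordinate on that axis is
    positive. Stress is the normalized residual between input and
    embedded distances (0 for an exactly embeddable matrix; 0 as well
    for an all-zero matrix, whose points coincide at the origin).
    """
    frame = dist.dist if isinstance(dist, StrainDistanceSet) else dist
    D = frame.to_numpy(dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    lam = np.clip(w[:2], 0.0, None)
    X = V[:, :2] * np.sqrt(lam)[None, :]
    for j in range(2):
        col = X[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            X[:, j] = -col
    emb = np.sqrt(
        np.maximum(
            ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2),
            0.0,
        )
    )
    denom = (D**2).sum()
    stress = float(np.sqrt(((D - emb) ** 2).sum() / denom)) if denom > 0 else 0.0
    return MdsEmbedding(
        coords=pd.DataFrame(X, index=frame.index, columns=["x", "y"]),
        stress=stress,
        eigenvalues=w,
    )


@dataclass
class DeviationCurve:
    """Per-time 1 - Spearman(WT, mutant); the strain's deviation trajectory."""

    strain_id: str
    values: pd.Series  # index time_h -> distance
    max_deviation_time_h: float

    def __post_init__(self) -> None:
        peak = self.values.max()
        if not np.isclose(self.values.loc[self.max_deviation_time_h], peak):
            raise ValueError("max_deviation_time_h does not attain the maximum")

    @property
    def flat_range(self) -> float:
        return float(self.values.max() - self.values.min())


def deviation_curve(
    profiles: StrainProfileSet, wt_id: str, strain_id: str
) -> DeviationCurve:
    """Distance of one mutant from wild type at every time point.

    The recorded maximum-deviation time breaks ties toward the earliest
    time point.
    """
    vals = {}
    for t in profiles.time_points_h:
        try:
            vals[t] = spearman_distance(
                profiles.vector(wt_id, t), profiles.vector(strain_id, t)
            )
        except ConstantProfileError as err:
            raise ConstantProfileError(
                f"constant profile at {t} h for {wt_id!r}/{strain_id!r}: {err}"
            ) from err
    series = pd.Series(vals).sort_index()
    max_t = float(series.index[np.argmax(series.to_numpy())])  # earliest on ties
    return DeviationCurve(strain_id=strain_id, values=series, max_deviation_time_h=max_t)


@dataclass
class TimingCall:
    """Relation between a gene's wild-type abundance peak and the mutant's
    maximal phenotype deviation."""

    strain_id: str
    gene_id: str | None
    peak_time_h: float
    max_deviation_time_h: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in TIMING_CATEGORIES:
            raise ValueError(f"unknown timing category {self.category!r}")


def timing_category(
    wt_profile_of_gene: pd.Series,
    deviation: DeviationCurve,
    flatness_epsilon: float = 0.05,
    gene_id: str | None = None,
) -> TimingCall:
    """Classify peak-abundance time against maximal-deviation time.

    ``wt_profile_of_gene`` maps time (h) to wild-type mean abundance of the
    gene mutated in the strain. The peak time is the argmax (earliest on
    ties). If the deviation curve is flat — range below
    ``flatness_epsilon`` — the call is ``no_correlation``; otherwise the
    peak either precedes, equals, or succeeds the maximal deviation.
    """
    prof = wt_profile_of_gene.sort_index()
    peak_t = float(prof.index[np.argmax(prof.to_numpy())])
    if deviation.flat_range < flatness_epsilon:
        cat = "no_correlation"
    elif peak_t < deviation.max_deviation_time_h:
        cat = "precedes"
    elif peak_t == deviation.max_deviation_time_h:
        cat = "equals"
    else:
        cat = "succeeds"
    return TimingCall(
        strain_id=deviation.strain_id,
        gene_id=gene_id,
        peak_time_h=peak_t,
        max_deviation_time_h=deviation.max_deviation_time_h,
        category=cat,
    )


def timing_table(
    profiles: StrainProfileSet,
    wt_id: str,
    mutated_gene_of_strain: dict,
    flatness_epsilon: float = 0.05,
) -> pd.DataFrame:
    """Timing calls for every mutant with a known mutated gene.

    The peak time is taken from the wild-type mean profile (RPKM) of the
    strain's own mutated gene.
    """
    rows = []
    for strain, gene in mutated_gene_of_strain.items():
        dev = deviation_curve(profiles, wt_id, strain)
        wt_prof = profiles.gene_profile(gene, wt_id)
        call = timing_category(wt_prof, dev, flatness_epsilon, gene_id=gene)
        rows.append(
            {
                "strain": strain,
                "gene_id": gene,
                "peak_time_h": call.peak_time_h,
                "max_deviation_time_h": call.max_deviation_time_h,
                "category": call.category,
            }
        )
    return pd.DataFrame(rows).set_index("strain")
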