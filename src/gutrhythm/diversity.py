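"""Feature-table filtering, bootstrapped alpha/beta diversity, genus
collapsing and principal coordinates analysis.

Conventions (documented because implementations differ):

- Shannon entropy in bits (log base 2); Pielou evenness uses the same base
  so it lies in [0, 1], and is missing for samples with < 2 observed features.
- Faith PD counts the branch length of the minimal subtree connecting the
  root and all observed tips (the root connection is included).
- Weighted UniFrac is the non-normalized variant by default.
- Rarefaction subsamples without replacement to exactly ``depth``; the
  random stream for each (sample, replicate) pair is derived from
  ``(seed, crc32(sample_id), replicate)`` so that subsetting samples never
  changes other samples' draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

from gutrhythm.datamodel import (
    ALPHA_METRICS,
    BETA_METRICS,
    FeatureTable,
    RootedTree,
    TaxonomyMap,
)
from gutrhythm.errors import GutRhythmError, IntegrityError


# ---------------------------------------------------------------------------
# result containers


@dataclass
class AlphaResult:
    sample_id: str
    metric: str
    value: float | None


class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over labeled samples."""

    def __init__(self, sample_ids: Sequence[str], data: np.ndarray, metric: str):
        data = np.asarray(data, dtype=float)
        n = len(sample_ids)
        if data.shape != (n, n):
            raise IntegrityError(f"distance matrix shape {data.shape} != ({n},{n})")
        if not np.allclose(data, data.T, atol=1e-12, rtol=0):
            raise IntegrityError("distance matrix not symmetric within 1e-12")
        data = (data + data.T) / 2.0
        np.fill_diagonal(data, 0.0)
        with np.errstate(invalid="ignore"):
            low = np.nanmin(data) if data.size else 0.0
        if low < -1e-9:
            raise IntegrityError("negative distances")
        if low < 0:  # float fuzz from matrix algebra
            data = np.maximum(data, 0.0)
        self.sample_ids = list(sample_ids)
        self.data = data
        self.metric = metric
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def submatrix(self, sample_ids: Sequence[str]) -> np.ndarray:
        idx = [self._index[s] for s in sample_ids]
        return self.data[np.ix_(idx, idx)]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.data[self._index[pair[0]], self._index[pair[1]]])


@dataclass
class PcoaEmbedding:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples × n_axes
    eigenvalues: np.ndarray  # retained, descending, > 0

    def coords_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return self.coordinates[[index[s] for s in sample_ids]]


@dataclass
class ExclusionRecord:
    entity: str  # "feature" or "sample"
    entity_id: str
    reason: str


# ---------------------------------------------------------------------------
# filtering


def filter_table(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    min_feature_total: int = 10,
    min_depth: int = 3035,
    order: Sequence[str] = ("phylum", "feature_total", "sample_depth"),
) -> tuple[FeatureTable, list[ExclusionRecord]]:
    """Apply the table filters in the configured order.

    Default order: (1) drop features with unassigned phylum, (2) drop
    features with total count < *min_feature_total*, (3) drop samples whose
    post-filter depth is < *min_depth*.
    """
    report: list[ExclusionRecord] = []
    current = table
    for step in order:
        if step == "phylum":
            keep = [f for f in current.feature_ids if taxonomy.has_phylum(f)]
            for f in current.feature_ids:
                if not taxonomy.has_phylum(f):
                    report.append(ExclusionRecord("feature", f, "phylum unassigned"))
            current = current.subset(feature_ids=keep)
        elif step == "feature_total":
            totals = current.feature_totals()
            keep = [
                f
                for f, t in zip(current.feature_ids, totals)
                if t >= min_feature_total
            ]
            for f, t in zip(current.feature_ids, totals):
                if t < min_feature_total:
                    report.append(
                        ExclusionRecord(
                            "feature", f, f"total count {t} < {min_feature_total}"
                        )
                    )
            current = current.subset(feature_ids=keep)
        elif step == "sample_depth":
            depths = current.sample_depths()
            keep = [
                s for s, d in zip(current.sample_ids, depths) if d >= min_depth
            ]
            for s, d in zip(current.sample_ids, depths):
                if d < min_depth:
                    report.append(
                        ExclusionRecord("sample", s, f"depth {d} < {min_depth}")
                    )
            current = current.subset(sample_ids=keep)
        else:
            raise GutRhythmError(f"unknown filter step {step!r}")
    if current.n_samples == 0:
        raise GutRhythmError("no samples retained after filtering")
    return current, report


# ---------------------------------------------------------------------------
# rarefaction


def _sub_rng(seed: int, sample_id: str, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(sample_id.encode()), replicate])
    )

def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector without replacement to exactly *depth*."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise GutRhythmError(f"sample depth {total} below rarefaction depth {depth}")
    if total == depth:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


# ---------------------------------------------------------------------------
# alpha kernels


def _branch_structure(
    tree: RootedTree, feature_ids: Sequence[str]
) -> tuple[sp.csr_matrix, np.ndarray]:
    cols = tree.tip_columns(feature_ids)
    return tree.incidence[:, cols].tocsr(), tree.branch_lengths


def alpha_kernels(
    counts: np.ndarray,
    tree: RootedTree | None = None,
    feature_ids: Sequence[str] | None = None,
) -> dict[str, float | None]:
    """Alpha metrics for a single count vector.

    faith_pd is computed only when *tree* and *feature_ids* are given.
    An all-zero vector yields all-missing metrics.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    out: dict[str, float | None] = {m: None for m in ALPHA_METRICS}
    if total == 0:
        return out
    nz = counts > 0
    observed = int(nz.sum())
    p = counts[nz] / total
    shannon = float(-(p * np.log2(p)).sum())
    out["observed_features"] = float(observed)
    out["shannon"] = shannon
    out["pielou"] = shannon / np.log2(observed) if observed >= 2 else None
    if tree is not None and feature_ids is not None:
        incidence, lengths = _branch_structure(tree, feature_ids)
        below = incidence @ nz.astype(float)
        out["faith_pd"] = float(lengths[below > 0].sum())
    return out


def _alpha_matrix(
    X: np.ndarray, incidence: sp.csr_matrix | None, lengths: np.ndarray | None
) -> dict[str, np.ndarray]:
    """Vectorized alpha metrics over rows of a count matrix (NaN = missing)."""
    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=1)
    nz = X > 0
    observed = nz.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = X / totals[:, None]
        terms = np.where(nz, -P * np.log2(np.where(nz, P, 1.0)), 0.0)
        shannon = terms.sum(axis=1)
        pielou = np.where(observed >= 2, shannon / np.log2(observed), np.nan)
    empty = totals == 0
    observed[empty] = np.nan
    shannon[empty] = np.nan
    pielou[empty] = np.nan
    out = {"observed_features": observed, "shannon": shannon, "pielou": pielou}
    if incidence is not None:
        below = nz.astype(float) @ incidence.T.toarray() > 0
        faith = below @ lengths
        faith[empty] = np.nan
        out["faith_pd"] = faith
    return out


def bootstrapped_alpha(
    table: FeatureTable,
    tree: RootedTree,
    depth: int = 3035,
    n_boot: int = 100,
    seed: int = 0,
) -> list[AlphaResult]:
    """Mean of each alpha metric over *n_boot* independent rarefactions."""
    depths = table.sample_depths()
    shallow = [
        s for s, d in zip(table.sample_ids, depths) if d < depth
    ]
    if shallow:
        raise GutRhythmError(
            f"samples below rarefaction depth {depth}: {shallow[:10]} "
            "(filter the table first)"
        )
    incidence, lengths = _branch_structure(tree, table.feature_ids)
    results: list[AlphaResult] = []
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        R = np.stack(
            [rarefy(counts, depth, _sub_rng(seed, sid, b)) for b in range(n_boot)]
        )
        metrics = _alpha_matrix(R, incidence, lengths)
        for m in ALPHA_METRICS:
            vals = metrics[m]
            defined = vals[~np.isnan(vals)]
            results.append(
                AlphaResult(sid, m, float(defined.mean()) if defined.size else None)
            )
    return results


# ---------------------------------------------------------------------------
# beta kernels


def _beta_matrices(
    X: np.ndarray,
    incidence: sp.csr_matrix | None,
    lengths: np.ndarray | None,
    metrics: Sequence[str],
    weighted_normalized: bool = False,
) -> dict[str, np.ndarray]:
    """All pairwise distances over rows of a count matrix, one matrix per metric."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    out: dict[str, np.ndarray] = {}
    if "bray_curtis" in metrics:
        out["bray_curtis"] = squareform(pdist(X, "braycurtis"))
    if "jaccard" in metrics:
        out["jaccard"] = squareform(pdist(X > 0, "jaccard"))
    needs_tree = {"unweighted_unifrac", "weighted_unifrac"} & set(metrics)
    if needs_tree:
        if incidence is None:
            raise GutRhythmError("UniFrac metrics require a tree")
        below = X @ incidence.T.toarray()
        if "unweighted_unifrac" in metrics:
            P = (below > 0).astype(float)
            Pl = P * lengths
            shared = Pl @ P.T
            tu = Pl.sum(axis=1)
            union = tu[:, None] + tu[None, :] - shared
            with np.errstate(invalid="ignore", divide="ignore"):
                d = (union - shared) / union
            d[union == 0] = np.nan
            np.fill_diagonal(d, 0.0)
            out["unweighted_unifrac"] = d
        if "weighted_unifrac" in metrics:
            totals = X.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                Q = below / totals[:, None]
            Q = np.nan_to_num(Q)
            d = squareform(pdist(Q * lengths, "cityblock"))
            if weighted_normalized:
                t = (Q * lengths).sum(axis=1)
                denom = t[:, None] + t[None, :]
                with np.errstate(invalid="ignore", divide="ignore"):
                    d = d / denom
                d[denom == 0] = np.nan
                np.fill_diagonal(d, 0.0)
            out["weighted_unifrac"] = d
    for m in out:
        np.fill_diagonal(out[m], 0.0)
    assert all(out[m].shape == (n, n) for m in out)
    return out


def beta_kernels(
    u: np.ndarray,
    v: np.ndarray,
    tree: RootedTree | None = None,
    feature_ids: Sequence[str] | None = None,
    weighted_normalized: bool = False,
) -> dict[str, float | None]:
    """All four beta metrics between two count vectors (missing when undefined)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.sum() == 0 and v.sum() == 0:
        return {m: None for m in BETA_METRICS}
    if tree is not None and feature_ids is not None:
        incidence, lengths = _branch_structure(tree, feature_ids)
        metrics = BETA_METRICS
    else:
        incidence, lengths = None, None
        metrics = ("bray_curtis", "jaccard")
    mats = _beta_matrices(
        np.stack([u, v]), incidence, lengths, metrics, weighted_normalized
    )
    out: dict[str, float | None] = {m: None for m in BETA_METRICS}
    for m, mat in mats.items():
        val = mat[0, 1]
        out[m] = None if np.isnan(val) else float(val)
    return out


def bootstrapped_beta(
    table: FeatureTable,
    tree: RootedTree,
    depth: int = 3035,
    n_boot: int = 100,
    seed: int = 0,
    metrics: Sequence[str] = BETA_METRICS,
    weighted_normalized: bool = False,
) -> dict[str, DistanceMatrix]:
    """Element-wise mean of *n_boot* rarefied distance matrices per metric."""
    depths = table.sample_depths()
    shallow = [s for s, d in zip(table.sample_ids, depths) if d < depth]
    if shallow:
        raise GutRhythmError(
            f"samples below rarefaction depth {depth}: {shallow[:10]}"
        )
    incidence, lengths = _branch_structure(tree, table.feature_ids)
    n = table.n_samples
    acc = {m: np.zeros((n, n)) for m in metrics}
    for b in range(n_boot):
        R = np.stack(
            [
                rarefy(table.counts[i], depth, _sub_rng(seed, sid, b))
                for i, sid in enumerate(table.sample_ids)
            ]
        )
        mats = _beta_matrices(R, incidence, lengths, metrics, weighted_normalized)
        for m in metrics:
            acc[m] += mats[m]
    return {
        m: DistanceMatrix(table.sample_ids, acc[m] / n_boot, m) for m in metrics
    }


# ---------------------------------------------------------------------------
# genus collapsing


def genus_label(taxonomy: TaxonomyMap, feature_id: str) -> str:
    genus = taxonomy.genus(feature_id) if feature_id in taxonomy else ""
    if genus:
        return genus
    if feature_id in taxonomy:
        _, finest = taxonomy.finest_rank(feature_id)
        return f"unclassified_{finest}" if finest else "unclassified_unknown"
    return "unclassified_unknown"


def collapse_to_genus(
    table: FeatureTable, taxonomy: TaxonomyMap, top_k: int = 5
) -> tuple[pd.DataFrame, list[str]]:
    """Sum ASV counts by genus; return samples × genus relative abundances
    and the top-*k* genera by mean relative abundance."""
    if len(taxonomy) == 0:
        raise GutRhythmError("empty taxonomy")
    labels = [genus_label(taxonomy, f) for f in table.feature_ids]
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=labels)
    collapsed = df.T.groupby(level=0).sum().T  # samples × genus
    depths = collapsed.sum(axis=1)
    rel = collapsed.div(depths, axis=0)
    top = list(rel.mean(axis=0).sort_values(ascending=False).index[:top_k])
    return rel, top


# ---------------------------------------------------------------------------
# PCoA


def pcoa(
    dm: DistanceMatrix, n_axes: int = 3, allow_fewer: bool = False
) -> PcoaEmbedding:
    """Classical metric MDS via Gower double-centering of −½D².

    Negative eigenvalues are not corrected, simply not retained. Axis signs
    are fixed so each axis's largest-magnitude coordinate is positive.
    """
    D = dm.data
    n = D.shape[0]
    if not allow_fewer and n < n_axes + 1:
        raise GutRhythmError(
            f"PCoA with {n_axes} axes needs ≥ {n_axes + 1} samples, got {n}"
        )
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0)) if n else 0.0
    n_pos = int((eigvals > tol).sum())
    if n_pos < n_axes:
        if not allow_fewer:
            raise GutRhythmError(
                f"only {n_pos} positive eigenvalues, need {n_axes}"
            )
        n_axes = n_pos
    vals = eigvals[:n_axes]
    coords = eigvecs[:, :n_axes] * np.sqrt(vals)
    for j in range(coords.shape[1]):
        k = int(np.argmax(np.abs(coords[:, j])))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return PcoaEmbedding(list(dm.sample_ids), coords, vals)
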