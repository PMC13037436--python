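"""Shared data contracts for the analysis pipeline.

All container types validate their invariants on construction so that
downstream stages can assume well-formed inputs.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from skbio import TreeNode

from gutrhythm.errors import IntegrityError

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

AGE_GROUPS = (2, 4, 6)

ALPHA_METRICS = ("observed_features", "shannon", "pielou", "faith_pd")
BETA_METRICS = ("bray_curtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


@dataclass(frozen=True, order=True)
class InfantAgeKey:
    """Grouping key for every per-infant-per-age aggregate."""

    infant_id: str
    age_group: int

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise IntegrityError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}"
            )


class FeatureTable:
    """Samples × features matrix of nonnegative integer counts.

    Parameters
    ----------
    sample_ids, feature_ids
        Unique row/column labels.
    counts
        Integer matrix, shape ``(len(sample_ids), len(feature_ids))``.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        feature_ids: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        sample_ids = list(map(str, sample_ids))
        feature_ids = list(map(str, feature_ids))
        if len(set(sample_ids)) != len(sample_ids):
            dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise IntegrityError(f"duplicate sample ids: {dups}")
        if len(set(feature_ids)) != len(feature_ids):
            dups = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
            raise IntegrityError(f"duplicate feature ids: {dups}")
        counts = np.asarray(counts)
        if counts.shape != (len(sample_ids), len(feature_ids)):
            raise IntegrityError(
                f"counts shape {counts.shape} does not match "
                f"{len(sample_ids)} samples × {len(feature_ids)} features"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise IntegrityError("counts must be integral")
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            raise IntegrityError("counts must be nonnegative")
        self.sample_ids = sample_ids
        self.feature_ids = feature_ids
        self.counts = counts
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}
        self._feature_index = {f: j for j, f in enumerate(feature_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sample_depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def feature_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self._sample_index[sample_id]]

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        feature_ids: Sequence[str] | None = None,
    ) -> "FeatureTable":
        rows = (
            [self._sample_index[s] for s in sample_ids]
            if sample_ids is not None
            else slice(None)
        )
        cols = (
            [self._feature_index[f] for f in feature_ids]
            if feature_ids is not None
            else slice(None)
        )
        sids = list(sample_ids) if sample_ids is not None else list(self.sample_ids)
        fids = list(feature_ids) if feature_ids is not None else list(self.feature_ids)
        return FeatureTable(sids, fids, self.counts[rows][:, cols])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FeatureTable)
            and self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )


class TaxonomyMap:
    """Feature id → ordered rank labels (domain … genus), missing ranks empty."""

    def __init__(self, mapping: Mapping[str, Sequence[str]]) -> None:
        self._ranks: dict[str, tuple[str, ...]] = {}
        for fid, ranks in mapping.items():
            ranks = tuple(str(r) for r in ranks)
            if len(ranks) > len(RANKS):
                raise IntegrityError(
                    f"feature {fid!r}: {len(ranks)} rank labels exceed {len(RANKS)}"
                )
            ranks = ranks + ("",) * (len(RANKS) - len(ranks))
            self._ranks[str(fid)] = ranks

    def __contains__(self, fid: str) -> bool:
        return fid in self._ranks

    def __len__(self) -> int:
        return len(self._ranks)

    def feature_ids(self) -> list[str]:
        return list(self._ranks)

    def ranks(self, fid: str) -> tuple[str, ...]:
        return self._ranks[fid]

    def rank(self, fid: str, rank_name: str) -> str:
        return self._ranks[fid][RANKS.index(rank_name)]

    def phylum(self, fid: str) -> str:
        return self._ranks[fid][1]

    def has_phylum(self, fid: str) -> bool:
        return bool(self._ranks.get(fid, ("",) * 6)[1])

    def genus(self, fid: str) -> str:
        return self._ranks[fid][5]

    def finest_rank(self, fid: str) -> tuple[str, str]:
        """(rank name, label) of the deepest non-empty rank, or ('', '')."""
        ranks = self._ranks[fid]
        for name, label in zip(reversed(RANKS), reversed(ranks)):
            if label:
                return name, label
        return "", ""

    def items(self):
        return self._ranks.items()


class RootedTree:
    """Rooted phylogeny with unique tip labels and nonnegative branch lengths.

    Wraps a :class:`skbio.TreeNode` and precomputes, for fast vectorized
    phylogenetic metrics, the branch-length vector and the sparse
    branch × tip incidence structure (incidence[b, t] = 1 iff tip *t* lies
    below branch *b*; the root carries no branch).
    """

    def __init__(self, tree: TreeNode) -> None:
        self._tree = tree
        tips = list(tree.tips())
        names = [t.name for t in tips]
        if any(n is None for n in names):
            raise IntegrityError("tree has unnamed tips")
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise IntegrityError(f"duplicate tip labels: {dups}")
        self.tip_names = names
        self._tip_col = {n: j for j, n in enumerate(names)}

        # postorder over non-root nodes; accumulate tip sets bottom-up
        nodes = [n for n in tree.postorder(include_self=False)]
        lengths = np.array(
            [0.0 if n.length is None else float(n.length) for n in nodes]
        )
        if lengths.size and lengths.min() < 0:
            raise IntegrityError("negative branch length in tree")
        rows: list[int] = []
        cols: list[int] = []
        below: dict[int, list[int]] = {}
        for b, node in enumerate(nodes):
            if node.is_tip():
                below[id(node)] = [self._tip_col[node.name]]
            else:
                acc: list[int] = []
                for child in node.children:
                    acc.extend(below.pop(id(child)))
                below[id(node)] = acc
            for t in below[id(node)]:
                rows.append(b)
                cols.append(t)
        self.branch_lengths = lengths
        self.incidence = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(nodes), len(names)),
        )

    @classmethod
    def from_newick(cls, source: str) -> "RootedTree":
        return cls(TreeNode.read(_io.StringIO(source)))

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self._tree.write(buf)
        return buf.getvalue()

    def tip_columns(self, feature_ids: Iterable[str]) -> np.ndarray:
        """Column indices of *feature_ids* in the incidence matrix."""
        missing = [f for f in feature_ids if f not in self._tip_col]
        if missing:
            raise IntegrityError(
                f"feature ids missing from tree tips: {sorted(missing)[:10]}"
            )
        return np.array([self._tip_col[f] for f in feature_ids], dtype=np.intp)

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())


@dataclass
class SampleRecord:
    """Metadata for one stool sample."""

    sample_id: str
    infant_id: str
    age_group: int
    age_days: int
    collection_datetime: datetime
    sex: str
    melatonin_pg_per_g: float | None = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise IntegrityError(
                f"sample {self.sample_id!r}: age_group {self.age_group!r} "
                f"not in {AGE_GROUPS}"
            )
        if self.age_days <= 0:
            raise IntegrityError(f"sample {self.sample_id!r}: age_days must be > 0")
        if self.sex not in ("female", "male"):
            raise IntegrityError(
                f"sample {self.sample_id!r}: sex must be female/male, got {self.sex!r}"
            )
        if self.melatonin_pg_per_g is not None and self.melatonin_pg_per_g < 0:
            raise IntegrityError(
                f"sample {self.sample_id!r}: melatonin must be nonnegative"
            )

    @property
    def key(self) -> InfantAgeKey:
        return InfantAgeKey(self.infant_id, self.age_group)


@dataclass
class QuestionnaireRecord:
    """Per infant-age questionnaire scores (BISQ variables, BCQ, ASQ)."""

    infant_id: str
    age_group: int
    bisq_night_sleep_h: float | None = None
    bisq_latency_h: float | None = None
    bisq_bedtime_clock_h: float | None = None
    bisq_n_awakenings: float | None = None
    bcq_attunement: float | None = None
    asq_composite: float | None = None

    @property
    def key(self) -> InfantAgeKey:
        return InfantAgeKey(self.infant_id, self.age_group)


@dataclass
class ActivitySeries:
    """Epoch-level actimetry for one infant-age on a regular time grid."""

    key: InfantAgeKey
    epoch_start: list[datetime]
    activity: np.ndarray
    wear: np.ndarray
    epoch_minutes: int = 1

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        n = len(self.epoch_start)
        if self.activity.shape != (n,) or self.wear.shape != (n,):
            raise IntegrityError("activity/wear length mismatch with epoch grid")
        if n and (not np.all(np.isfinite(self.activity)) or self.activity.min() < 0):
            raise IntegrityError("activity must be finite and nonnegative")
        if n > 1:
            deltas = {
                (b - a).total_seconds()
                for a, b in zip(self.epoch_start[:-1], self.epoch_start[1:])
            }
            if deltas != {self.epoch_minutes * 60.0}:
                raise IntegrityError(
                    f"epoch grid irregular for {self.key}: deltas {sorted(deltas)[:3]}"
                )


@dataclass
class SleepBout:
    start: datetime
    end: datetime


@dataclass
class DiaryTimeline:
    """15-min sleep/wake diary plus feeding times for one infant-age."""

    key: InfantAgeKey
    interval_start: list[datetime]
    is_sleep: np.ndarray  # bool per 15-min interval
    feed_times: list[datetime] = field(default_factory=list)
    interval_minutes: int = 15

    def __post_init__(self) -> None:
        self.is_sleep = np.asarray(self.is_sleep, dtype=bool)
        if len(self.interval_start) != len(self.is_sleep):
            raise IntegrityError("diary state length mismatch")
        self.feed_times = sorted(self.feed_times)

    def sleep_bouts(self) -> list[SleepBout]:
        """Maximal runs of consecutive sleep intervals as [start, end)."""
        bouts: list[SleepBout] = []
        n = len(self.interval_start)
        i = 0
        from datetime import timedelta

        step = timedelta(minutes=self.interval_minutes)
        while i < n:
            if self.is_sleep[i]:
                j = i
                while j + 1 < n and self.is_sleep[j + 1]:
                    j += 1
                bouts.append(
                    SleepBout(self.interval_start[i], self.interval_start[j] + step)
                )
                i = j + 1
            else:
                i += 1
        return bouts
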