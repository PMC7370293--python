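"""Train/test construction, class-imbalance sampling and grid enumeration.

The experimental design this module reproduces works on a heavily imbalanced
corpus of positive and negative protein pairs:

* a domain-aware train/test split that keeps the majority of each domain
  combination in training (so every test domain was seen in training),
* random undersampling of the majority (positive) class to 1:1, 2:1 or 3:1
  against the negatives,
* SMOTE oversampling of the minority (negative) class to 2x or 3x, seeded
  from the 1:1 undersample,
* redundancy removal (no duplicate feature vectors within a partition, no
  train vector repeated in test),
* enumeration of the full sampling grid: 8 representation combinations
  (cutoff 7/8 Å x SC/noSC x sum/concat) x 3 under-ratios x 3 replicates x 3
  scalings = 216 training sets, plus 8 x 2 over-factors x 3 replicates x 3
  scalings = 144, totalling 360; and 2 x 2 x 2 x 3 = 24 test sets.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .ppi_features import NEGATIVE, POSITIVE

UNDER_RATIOS = (1, 2, 3)
OVER_FACTORS = (2, 3)


@dataclass(frozen=True)
class PPIDataset:
    """A labelled feature table plus provenance."""

    features: np.ndarray  # (n, d) float
    labels: np.ndarray  # (n,) of {"positive", "negative"}
    pair_ids: tuple[tuple[str, str], ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.atleast_2d(np.asarray(self.features, dtype=float)))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels must have the same length")
        bad = set(self.labels) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == POSITIVE))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == NEGATIVE))

    def subset(self, idx: np.ndarray) -> "PPIDataset":
        ids = tuple(self.pair_ids[i] for i in idx) if self.pair_ids else ()
        return PPIDataset(self.features[idx], self.labels[idx], ids, dict(self.provenance))

    def class_composition(self) -> dict[str, float]:
        """Percent of instances per class, to one decimal."""
        n = len(self)
        return {
            POSITIVE: round(100.0 * self.n_positive / n, 1),
            NEGATIVE: round(100.0 * self.n_negative / n, 1),
        }


@dataclass(frozen=True)
class SamplingGridSpec:
    """Cross-product description of the sampling experiment."""

    cutoffs: tuple[float, ...] = (7, 8)
    atom_modes: tuple[str, ...] = ("SC", "noSC")
    combine_modes: tuple[str, ...] = ("sum", "concat")
    under_ratios: tuple[int, ...] = UNDER_RATIOS
    over_factors: tuple[int, ...] = OVER_FACTORS
    replicates: int = 3
    scalings: tuple[str, ...] = ("raw", "normalize", "standardize")
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(r < 1 for r in self.under_ratios) or any(f < 2 for f in self.over_factors):
            raise ValueError("ratios must be positive (over-factors >= 2)")


@dataclass(frozen=True)
class TrainingConfig:
    """One cell of the training grid."""

    cutoff: float
    atom_mode: str
    combine_mode: str
    branch: str  # "undersample" | "oversample"
    ratio: int  # pos-per-neg ratio (under) or negative multiplication factor (over)
    replicate: int
    scaling: str
    seed: int

    @property
    def sampling_tag(self) -> str:
        return f"{self.ratio}:1" if self.branch == "undersample" else f"1:{self.ratio}"

    @property
    def label(self) -> str:
        return (
            f"{self.cutoff:g}A_{self.atom_mode}_{self.combine_mode}_"
            f"{self.branch}_{self.sampling_tag}_rep{self.replicate}_{self.scaling}"
        )


@dataclass(frozen=True)
class TestConfig:
    cutoff: float
    atom_mode: str
    combine_mode: str
    scaling: str

    @property
    def label(self) -> str:
        return f"{self.cutoff:g}A_{self.atom_mode}_{self.combine_mode}_{self.scaling}"


def derive_seed(base_seed: int, *tokens) -> int:
    """Stable 31-bit seed derived from a base seed and context tokens."""
    text = ":".join([str(base_seed), *map(str, tokens)])
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def split_by_domain(
    pairs: list[tuple[str, str, str]],
    domain_annotations: dict[str, set[str]],
    negative_policy: str = "shared",
    seed: int = 0,
    test_fraction: float = 0.2,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Leakage-aware split of labelled pairs.

    Positive pairs are grouped by the (unordered) pair of their proteins'
    domain-set annotations; each group sends at most half of its pairs to
    test (largest groups first, later pairs to test), so every domain
    combination seen in test has at least as many training examples, and a
    combination observed once goes to training only.

    ``negative_policy="shared"`` copies every negative pair into both
    partitions (the redundant protocol); ``"split"`` instead performs a
    seeded 80/20 (by default) split of unique negatives.
    """
    positives = [p for p in pairs if p[2] == POSITIVE]
    negatives = [p for p in pairs if p[2] == NEGATIVE]
    groups: dict[tuple, list[tuple[str, str, str]]] = {}
    for a, b, lab in positives:
        for prot in (a, b):
            if prot not in domain_annotations or not domain_annotations[prot]:
                raise ValueError(f"missing domain annotation for protein {prot!r}")
        key = tuple(
            sorted([tuple(sorted(domain_annotations[a])), tuple(sorted(domain_annotations[b]))])
        )
        groups.setdefault(key, []).append((a, b, lab))

    train: list[tuple[str, str, str]] = []
    test: list[tuple[str, str, str]] = []
    for key in sorted(groups, key=lambda k: (-len(groups[k]), k)):
        members = groups[key]
        n_test = len(members) // 2
        train.extend(members[: len(members) - n_test])
        test.extend(members[len(members) - n_test :])

    if negative_policy == "shared":
        train.extend(negatives)
        test.extend(negatives)
    elif negative_policy == "split":
        uniq = list(dict.fromkeys(negatives))
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(uniq))
        n_test = int(round(test_fraction * len(uniq)))
        test.extend(uniq[i] for i in order[:n_test])
        train.extend(uniq[i] for i in order[n_test:])
    else:
        raise ValueError(f"unknown negative policy: {negative_policy!r}")
    return train, test


def undersample(dataset: PPIDataset, ratio_pos_per_neg: int, seed: int) -> PPIDataset:
    """Keep all negatives; sample positives down to ratio x negative count.

    Uniform sampling without replacement, deterministic under ``seed``.
    """
    if ratio_pos_per_neg < 1:
        raise ValueError("ratio must be a positive integer")
    pos_idx = np.flatnonzero(dataset.labels == POSITIVE)
    neg_idx = np.flatnonzero(dataset.labels == NEGATIVE)
    target = ratio_pos_per_neg * len(neg_idx)
    if len(pos_idx) < target:
        raise ValueError(
            f"cannot satisfy ratio {ratio_pos_per_neg}:1 — need {target} positives, "
            f"have {len(pos_idx)}"
        )
    rng = np.random.default_rng(seed)
    keep_pos = rng.choice(pos_idx, size=target, replace=False)
    idx = np.sort(np.concatenate([keep_pos, neg_idx]))
    out = dataset.subset(idx)
    prov = dict(out.provenance)
    prov.update(sampling=f"{ratio_pos_per_neg}:1", seed=seed)
    return replace(out, provenance=prov)


def smote_oversample(
    dataset: PPIDataset, factor: int, k_neighbors: int = 5, seed: int = 0
) -> PPIDataset:
    """Classical SMOTE on the minority class.

    The output contains one unmodified copy of every original instance plus
    (factor - 1) synthetic instances per minority point, each drawn on the
    segment x + u (z - x) toward one of x's k nearest minority neighbours
    (Euclidean), u uniform on [0, 1).
    """
    if factor < 2:
        raise ValueError("oversampling factor must be >= 2")
    counts = Counter(dataset.labels)
    # ties (a 1:1 sample) resolve to the negative class, the domain's minority
    minority = min((NEGATIVE, POSITIVE), key=lambda c: counts.get(c, 0))
    min_idx = np.flatnonzero(dataset.labels == minority)
    if len(min_idx) <= k_neighbors:
        raise ValueError(
            f"too few minority instances ({len(min_idx)}) for k={k_neighbors} SMOTE"
        )
    X = dataset.features[min_idx]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, neigh = nn.kneighbors(X)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    synth = []
    for rep in range(factor - 1):
        for i in range(len(X)):
            j = neigh[i, 1 + rng.integers(k_neighbors)]
            u = rng.random()
            synth.append(X[i] + u * (X[j] - X[i]))
    synth = np.array(synth)
    features = np.concatenate([dataset.features, synth])
    labels = np.concatenate([dataset.labels, np.full(len(synth), minority, dtype=object)])
    ids = tuple(dataset.pair_ids) + tuple(
        (f"synthetic_{minority}_{i}", "") for i in range(len(synth))
    ) if dataset.pair_ids else ()
    prov = dict(dataset.provenance)
    prov.update(oversampling=f"1:{factor}", smote_k=k_neighbors, seed=seed)
    return PPIDataset(features, labels, ids, prov)


def remove_redundancy(train: PPIDataset, test: PPIDataset) -> tuple[PPIDataset, PPIDataset]:
    """Deduplicate feature vectors and remove train/test overlap.

    Within each partition only the first occurrence of a feature vector is
    kept; any test vector that also appears in train is dropped from test.
    """
    if train.features.shape[1] != test.features.shape[1]:
        raise ValueError("train and test must share feature length")

    def dedupe(ds: PPIDataset) -> PPIDataset:
        seen, keep = set(), []
        for i, row in enumerate(ds.features):
            key = tuple(row)
            if key not in seen:
                seen.add(key)
                keep.append(i)
        return ds.subset(np.array(keep, dtype=int))

    train_u = dedupe(train)
    test_u = dedupe(test)
    train_keys = {tuple(row) for row in train_u.features}
    keep = [i for i, row in enumerate(test_u.features) if tuple(row) not in train_keys]
    return train_u, test_u.subset(np.array(keep, dtype=int))


def enumerate_training_grid(spec: SamplingGridSpec) -> list[TrainingConfig]:
    """All training-set configurations of the sampling experiment.

    With the default spec this is 216 undersample-branch cells
    (8 x 3 ratios x 3 replicates x 3 scalings) followed by 144
    oversample-branch cells (8 x 2 factors x 3 replicates x 3 scalings).
    Oversample cells reuse the replicate's 1:1 undersample seed so the
    1:2/1:3 sets are derived from that sample.
    """
    configs: list[TrainingConfig] = []
    combos = [
        (c, m, cm)
        for c in spec.cutoffs
        for m in spec.atom_modes
        for cm in spec.combine_modes
    ]
    for cutoff, mode, combine_mode in combos:
        for ratio in spec.under_ratios:
            for rep in range(1, spec.replicates + 1):
                for scaling in spec.scalings:
                    configs.append(
                        TrainingConfig(
                            cutoff, mode, combine_mode, "undersample", ratio, rep,
                            scaling,
                            derive_seed(spec.base_seed, cutoff, mode, combine_mode,
                                        "under", ratio, rep),
                        )
                    )
    for cutoff, mode, combine_mode in combos:
        for factor in spec.over_factors:
            for rep in range(1, spec.replicates + 1):
                for scaling in spec.scalings:
                    configs.append(
                        TrainingConfig(
                            cutoff, mode, combine_mode, "oversample", factor, rep,
                            scaling,
                            # derived from the replicate's 1:1 undersample
                            derive_seed(spec.base_seed, cutoff, mode, combine_mode,
                                        "under", 1, rep),
                        )
                    )
    return configs


def enumerate_test_grid(spec: SamplingGridSpec) -> list[TestConfig]:
    """Cross product cutoffs x atom modes x combine modes x scalings (24 by default)."""
    return [
        TestConfig(c, m, cm, s)
        for c in spec.cutoffs
        for m in spec.atom_modes
        for cm in spec.combine_modes
        for s in spec.scalings
    ]
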