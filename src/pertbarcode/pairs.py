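"""Compound-level splits and replicate / non-replicate pair sets.

Splits are made at the compound level so all replicates of a compound land in
one partition (otherwise the network could memorise samples instead of
learning the replicate relation).  Pair sets hold (sample_a, sample_b, label)
with label +1 for biological replicates and -1 otherwise, at a configurable
negative:positive ratio (default 2, i.e. replicate pairs are one third of the
training stream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleMetadata

__all__ = ["CompoundSplit", "PairSet", "split_by_compound", "sample_pairs",
           "pairs_to_stream"]


@dataclass
class CompoundSplit:
    train_compounds: list[str]
    validation_compounds: list[str]
    test_compounds: list[str]

    def __post_init__(self) -> None:
        parts = [set(self.train_compounds), set(self.validation_compounds),
                 set(self.test_compounds)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split partitions are not disjoint")


@dataclass
class PairSet:
    """Ordered list of labelled sample pairs."""

    pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b, label in self.pairs:
            if a == b:
                raise ValueError(f"pair of a sample with itself: {a!r}")
            if label not in (1, -1):
                raise ValueError(f"pair label must be +1 or -1, got {label}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([label for _, _, label in self.pairs])

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.pairs, columns=["sample_a", "sample_b", "label"]
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "PairSet":
        frame = pd.read_csv(path, sep="\t", dtype={"sample_a": str, "sample_b": str})
        return cls([(r.sample_a, r.sample_b, int(r.label))
                    for r in frame.itertuples(index=False)])


def split_by_compound(metadata: list[SampleMetadata],
                      fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                      seed: int = 0) -> CompoundSplit:
    """Partition compounds (not samples) into train/validation/test.

    Validation and test sizes are ``round(fraction * n)``; the remainder goes
    to train, approximating the 80/10/10 convention.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    compounds = sorted({m.compound_id for m in metadata if not m.is_vehicle})
    if len(compounds) < 3:
        raise ValueError("need at least 3 compounds to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(compounds))
    n = len(order)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    return CompoundSplit(train_compounds=sorted(order[n_val + n_test:]),
                         validation_compounds=sorted(order[:n_val]),
                         test_compounds=sorted(order[n_val:n_val + n_test]))


def sample_pairs(metadata: list[SampleMetadata],
                 compounds,
                 n_positive: int = 40000,
                 negative_ratio: int = 2,
                 seed: int = 0) -> PairSet:
    """Sample replicate (+1) and cross-compound (-1) pairs among ``compounds``.

    Positives are drawn uniformly without replacement from all
    within-replicate-group pairs; when fewer than ``n_positive`` exist, all
    are used and the negative count is ``negative_ratio`` times the actual
    positive count.  Negatives pair samples of *different* compounds.
    """
    compounds = set(compounds)
    rng = np.random.default_rng(seed)
    records = [m for m in metadata if m.compound_id in compounds and not m.is_vehicle]
    by_group: dict[str, list[str]] = {}
    for m in records:
        by_group.setdefault(m.replicate_group_id, []).append(m.sample_id)
    positive_pool: list[tuple[str, str]] = []
    for group in sorted(by_group):
        members = sorted(by_group[group])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                positive_pool.append((members[i], members[j]))
    if not positive_pool:
        raise ValueError("no replicate groups of size >= 2 among the given compounds")

    if len(positive_pool) <= n_positive:
        positives = list(positive_pool)
        rng.shuffle(positives)
    else:
        idx = rng.choice(len(positive_pool), size=n_positive, replace=False)
        positives = [positive_pool[i] for i in idx]

    n_negative = negative_ratio * len(positives)
    sample_list = sorted(m.sample_id for m in records)
    compound_of = {m.sample_id: m.compound_id for m in records}
    negatives: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_cross = _count_cross_compound_pairs(records)
    with_replacement = n_negative > n_cross
    if with_replacement:
        warnings.warn("cross-compound pair pool exhausted; sampling negatives "
                      "with replacement", stacklevel=2)
    attempts = 0
    while len(negatives) < n_negative:
        a, b = rng.choice(len(sample_list), size=2, replace=False)
        pair = (sample_list[min(a, b)], sample_list[max(a, b)])
        attempts += 1
        if compound_of[pair[0]] == compound_of[pair[1]]:
            continue
        if not with_replacement and pair in seen:
            continue
        seen.add(pair)
        negatives.append(pair)

    pairs = [(a, b, 1) for a, b in positives] + [(a, b, -1) for a, b in negatives]
    return PairSet(pairs)


def _count_cross_compound_pairs(records: list[SampleMetadata]) -> int:
    sizes: dict[str, int] = {}
    for m in records:
        sizes[m.compound_id] = sizes.get(m.compound_id, 0) + 1
    n = sum(sizes.values())
    same = sum(k * (k - 1) // 2 for k in sizes.values())
    return n * (n - 1) // 2 - same


def pairs_to_stream(matrix: ExpressionMatrix, pair_set: PairSet,
                    batch_size: int = 256, shuffle: bool = False,
                    seed: int = 0):
    """Yield (X, labels) minibatches with pair members as adjacent rows.

    ``batch_size`` counts rows and must be even: rows 2k and 2k+1 of a batch
    are the two members of its k-th pair, and ``labels[k]`` is that pair's
    label.  Shuffling permutes whole pairs and never splits one across
    batches.
    """
    if batch_size % 2 != 0:
        raise ValueError("batch_size must be even (pairs occupy adjacent rows)")
    col_index = {s: j for j, s in enumerate(matrix.sample_ids)}
    pairs = list(pair_set.pairs)
    if shuffle:
        rng = np.random.default_rng(seed)
        pairs = [pairs[i] for i in rng.permutation(len(pairs))]
    pairs_per_batch = batch_size // 2
    for start in range(0, len(pairs), pairs_per_batch):
        chunk = pairs[start:start + pairs_per_batch]
        cols: list[int] = []
        for a, b, _ in chunk:
            cols.append(col_index[a])
            cols.append(col_index[b])
        X = matrix.values[:, cols].T  # rows = samples
        labels = np.asarray([label for _, _, label in chunk])
        yield X, labels
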