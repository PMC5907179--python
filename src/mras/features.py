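"""l-gram (spectrum) feature extraction and per-column standardization.

Each sequence is mapped to the count vector of its contiguous length-l
substrings (overlaps counted).  The vocabulary is the union of l-mers
observed in the record set, sorted lexicographically, so two runs over
the same records always produce the same column order.  Raw counts are
then standardized column-wise, x' = (x - mean) / sd, using the
population standard deviation by default; constant columns become all
zeros rather than being dropped, which keeps indices stable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import SequenceRecord


@dataclass
class FeatureMatrix:
    entity_ids: list[str]
    lmer_vocabulary: list[str]
    values: np.ndarray  # |entities| x |vocabulary|
    l: int
    standardized: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.entity_ids, columns=self.lmer_vocabulary
        )


def count_lgrams(record: SequenceRecord | str, l: int) -> Counter:
    """Counts of every contiguous length-l substring (overlapping).

    A sequence shorter than l yields an empty counter.
    """
    if l < 1:
        raise ValueError(f"l must be >= 1, got {l}")
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    return Counter(seq[i : i + l] for i in range(len(seq) - l + 1))


def build_feature_matrix(records: Sequence[SequenceRecord], l: int) -> FeatureMatrix:
    """Raw l-gram count matrix over the observed vocabulary.

    All records must belong to one entity class (target and ncRNA
    features never mix: they feed separate kernels).  Records shorter
    than l contribute all-zero rows.  If no record reaches length l the
    result has zero columns.
    """
    if not records:
        raise ValueError("cannot build features from an empty record list")
    classes = {r.entity_class for r in records}
    if len(classes) > 1:
        raise ValueError(f"records mix entity classes: {sorted(classes)}")
    counts = [count_lgrams(r, l) for r in records]
    vocabulary = sorted(set().union(*[c.keys() for c in counts]))
    col = {mer: j for j, mer in enumerate(vocabulary)}
    values = np.zeros((len(records), len(vocabulary)), dtype=float)
    for i, c in enumerate(counts):
        for mer, k in c.items():
            values[i, col[mer]] = k
    return FeatureMatrix([r.id for r in records], vocabulary, values, l, False)


def standardize_features(fm: FeatureMatrix, ddof: int = 0) -> FeatureMatrix:
    """Column-wise standardization x' = (x - mean) / sd.

    ``ddof=0`` (population sd) is the default; ``ddof=1`` selects the
    sample sd.  Columns with zero variance are set to all zeros.
    """
    if fm.standardized:
        raise ValueError("feature matrix is already standardized")
    if fm.values.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    x = fm.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mean[nz]) / sd[nz]
    return FeatureMatrix(
        list(fm.entity_ids), list(fm.lmer_vocabulary), out, fm.l, True
    )
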