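"""Isobaric-tag channel design and reporter-ion purity matrices.

The study design quantified six samples in one 8-plex iTRAQ run: two
biological replicates each of room-air controls (C1, C2), hypoxia-adapted
flies (LOF1, LOF2) and hyperoxia-adapted flies (HOF1, HOF2), labeled with
reporters 113, 115, 116, 117, 118 and 119 respectively.  The purity matrix
describes cross-channel bleed of each reagent's isotopic envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

DEFAULT_CHANNEL_MAP: dict[str, int] = {
    "C1": 113,
    "C2": 115,
    "LOF1": 116,
    "LOF2": 117,
    "HOF1": 118,
    "HOF2": 119,
}

#: sample -> experimental group
GROUP_OF_SAMPLE: dict[str, str] = {
    "C1": "C", "C2": "C",
    "LOF1": "LOF", "LOF2": "LOF",
    "HOF1": "HOF", "HOF2": "HOF",
}


@dataclass(frozen=True)
class ChannelDesign:
    """Mapping of samples to reporter channels plus the reference sample.

    The reference sample anchors channel normalization (the control
    channel's median is the normalization target).
    """

    channel_map: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    reference_sample: str = "C1"

    def __post_init__(self) -> None:
        channels = list(self.channel_map.values())
        if len(set(channels)) != len(channels):
            raise ValueError("reporter channels must be distinct")
        if self.reference_sample not in self.channel_map:
            raise ValueError(
                f"reference sample {self.reference_sample!r} not in design")

    @property
    def samples(self) -> list[str]:
        return list(self.channel_map)

    @property
    def channels(self) -> list[int]:
        return [self.channel_map[s] for s in self.samples]

    def group_of(self, sample: str) -> str:
        return GROUP_OF_SAMPLE.get(sample, sample)


class PurityMatrix:
    """Square reporter-purity matrix over the used channels.

    ``P[i, j]`` is the fraction of channel-*j* reagent signal observed in
    channel *i*; the observed reporter vector is ``P @ true``.  Columns must
    sum to at most 1 (signal may bleed outside the monitored window) and the
    matrix must be diagonally dominant by columns, which is what vendor
    certificates guarantee in practice and what makes the correction
    well-posed.
    """

    def __init__(self, matrix: np.ndarray, channels: Sequence[int]):
        matrix = np.asarray(matrix, dtype=float)
        channels = list(channels)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("purity matrix must be square")
        if matrix.shape[0] != len(channels):
            raise ValueError("matrix size must match number of channels")
        if (matrix < 0).any():
            raise ValueError("purity matrix entries must be non-negative")
        colsum = matrix.sum(axis=0)
        if (colsum > 1 + 1e-9).any():
            raise ValueError("purity matrix columns must sum to <= 1")
        diag = np.diag(matrix)
        off = colsum - diag
        if (diag <= off).any():
            raise ValueError("purity matrix must be diagonally dominant")
        self.matrix = matrix
        self.channels = channels

    @classmethod
    def identity(cls, channels: Sequence[int]) -> "PurityMatrix":
        return cls(np.eye(len(list(channels))), channels)

    @classmethod
    def from_yaml(cls, path) -> "PurityMatrix":
        """Load a channel-labeled, row-major purity matrix from YAML."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        channels = [int(c) for c in doc["channels"]]
        matrix = np.asarray(doc["matrix"], dtype=float)
        return cls(matrix, channels)

    def to_yaml(self, path) -> None:
        doc = {
            "channels": self.channels,
            "matrix": [[float(v) for v in row] for row in self.matrix],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def reorder(self, channels: Sequence[int]) -> "PurityMatrix":
        """Return the matrix restricted/permuted to ``channels``."""
        idx = [self.channels.index(c) for c in channels]
        return PurityMatrix(self.matrix[np.ix_(idx, idx)], list(channels))

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (isinstance(other, PurityMatrix)
                and self.channels == other.channels
                and np.array_equal(self.matrix, other.matrix))
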