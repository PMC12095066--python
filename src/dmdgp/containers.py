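"""Core in-memory containers shared across the package.

Two objects travel through every stage of the workflow:

* :class:`GenotypeMatrix` — biallelic SNP dosages (0/1/2 alternate-allele
  counts) for a panel of lines; the predictor side of genomic prediction.
* :class:`TraitTensor` — line x trait x timepoint phenotype values on a
  days-after-sowing axis, with the measurement days partitioned into
  consecutive blocks (phenotyping platforms often skip days, e.g. 5-day
  weekly blocks separated by 2-day gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "TraitTensor", "infer_blocks"]


def infer_blocks(time_axis: np.ndarray) -> list[np.ndarray]:
    """Partition timepoint indices into runs of consecutive calendar days.

    A difference greater than one day between successive measurements starts
    a new block.
    """
    time_axis = np.asarray(time_axis)
    if time_axis.ndim != 1 or len(time_axis) == 0:
        raise ValueError("time_axis must be a non-empty 1-D array")
    if np.any(np.diff(time_axis) <= 0):
        raise ValueError("time_axis must be strictly increasing")
    breaks = np.flatnonzero(np.diff(time_axis) > 1) + 1
    return [np.asarray(b) for b in np.split(np.arange(len(time_axis)), breaks)]


@dataclass
class GenotypeMatrix:
    """SNP dosage matrix: k lines x m markers, entries in {0, 1, 2}."""

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # (k, m) integer

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        k, m = self.dosages.shape
        if len(self.line_ids) != k:
            raise ValueError(f"{len(self.line_ids)} line ids for {k} dosage rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} dosage columns")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids must be unique")
        if k < 2:
            raise ValueError("need at least 2 lines")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be alternate-allele counts in {0, 1, 2}")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, in [0, 0.5]."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def subset_lines(self, line_ids: list[str]) -> "GenotypeMatrix":
        index = {l: i for i, l in enumerate(self.line_ids)}
        rows = [index[l] for l in line_ids]
        return GenotypeMatrix(list(line_ids), list(self.marker_ids), self.dosages[rows])

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            list(self.line_ids),
            [self.marker_ids[j] for j in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.marker_ids[j] for j in keep],
            self.dosages[:, keep],
        )


@dataclass
class TraitTensor:
    """k lines x p traits x T timepoints of line-level trait values.

    ``time_axis`` holds integer calendar days (days after sowing);
    ``blocks`` partitions the T indices into consecutive measurement blocks.
    Missing values are represented by NaN and must be imputed (or rejected)
    before modelling.
    """

    line_ids: list[str]
    trait_ids: list[str]
    time_axis: np.ndarray  # (T,) int
    values: np.ndarray  # (k, p, T) float
    blocks: list[np.ndarray] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis)
        k, p, T = self.values.shape
        if len(self.line_ids) != k or len(self.trait_ids) != p or len(self.time_axis) != T:
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.line_ids)} lines, {len(self.trait_ids)} traits, "
                f"{len(self.time_axis)} timepoints"
            )
        if self.blocks is None:
            self.blocks = infer_blocks(self.time_axis)
        self._check_blocks()

    def _check_blocks(self) -> None:
        if np.any(np.diff(self.time_axis) <= 0):
            raise ValueError("time_axis must be strictly increasing")
        covered = np.concatenate(self.blocks) if self.blocks else np.array([], dtype=int)
        if not np.array_equal(covered, np.arange(len(self.time_axis))):
            raise ValueError("blocks must be disjoint, consecutive and cover all timepoints")
        for b in self.blocks:
            if len(b) > 1 and np.any(np.diff(self.time_axis[b]) != 1):
                raise ValueError("within a block, consecutive days must differ by exactly 1")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def line_matrix(self, line: str) -> np.ndarray:
        """The p x T trait-by-time matrix X for one line."""
        return self.values[self.line_ids.index(line)]

    def subset_lines(self, line_ids: list[str]) -> "TraitTensor":
        index = {l: i for i, l in enumerate(self.line_ids)}
        rows = [index[l] for l in line_ids]
        return TraitTensor(
            list(line_ids), list(self.trait_ids), self.time_axis.copy(),
            self.values[rows], [b.copy() for b in self.blocks],
        )

    def subset_timepoints(self, idx: np.ndarray) -> "TraitTensor":
        """Restrict to a prefix or general subset of timepoints (blocks re-inferred)."""
        idx = np.asarray(idx)
        return TraitTensor(
            list(self.line_ids), list(self.trait_ids), self.time_axis[idx],
            self.values[:, :, idx],
        )
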