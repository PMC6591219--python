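"""In-memory containers shared across the simulation and expression modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PositionalCounts", "CountMatrix"]


@dataclass
class PositionalCounts:
    """Per-transcript read counts binned by distance from the 3' end.

    ``counts[tid]`` is an integer array of shape (n_bins, n_samples) where bin
    ``i`` covers 3'-distances ``[i*bin_width, (i+1)*bin_width)`` (the last bin
    may be partial, ending at the transcript's spliced length).
    """

    bin_width: int
    samples: list[str]
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)
    length_of: dict[str, int] = field(default_factory=dict)

    def n_bins(self, transcript_id: str) -> int:
        length = self.length_of[transcript_id]
        return int(np.ceil(length / self.bin_width))

    def gene_totals(self) -> pd.DataFrame:
        """Sum positional counts over bins and transcripts -> gene x sample matrix."""
        genes = sorted(set(self.gene_of.values()))
        out = pd.DataFrame(0, index=genes, columns=self.samples, dtype=np.int64)
        for tid, arr in self.counts.items():
            out.loc[self.gene_of[tid]] += arr.sum(axis=0).astype(np.int64)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: transcript, bin_start, one column per sample."""
        rows = []
        for tid in sorted(self.counts):
            arr = self.counts[tid]
            starts = np.arange(arr.shape[0]) * self.bin_width
            block = pd.DataFrame(arr, columns=self.samples)
            block.insert(0, "bin_start", starts)
            block.insert(0, "transcript_id", tid)
            rows.append(block)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        bin_width: int,
        gene_of: dict[str, str],
        length_of: dict[str, int],
    ) -> "PositionalCounts":
        samples = [c for c in frame.columns if c not in ("transcript_id", "bin_start")]
        counts: dict[str, np.ndarray] = {}
        for tid, block in frame.groupby("transcript_id", sort=True):
            block = block.sort_values("bin_start")
            counts[str(tid)] = block[samples].to_numpy(dtype=np.int64)
        return cls(
            bin_width=bin_width,
            samples=samples,
            counts=counts,
            gene_of=dict(gene_of),
            length_of=dict(length_of),
        )


@dataclass
class CountMatrix:
    """Gene x sample counts plus the metadata normalization and DE need.

    ``values`` holds raw integers straight after counting and non-negative
    reals after TMM adjustment (pseudo-counts).  ``gene_lengths`` is the
    length over which reads were counted (truncated length when truncation was
    applied); ``full_lengths`` the original spliced transcript length used for
    length-binning.  ``lib_sizes`` defaults to column sums.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series
    full_lengths: pd.Series | None = None
    sample_info: pd.DataFrame | None = None
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        if not self.gene_lengths.index.equals(self.values.index):
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
        if self.gene_lengths.isna().any():
            raise ValueError("gene_lengths missing for some genes")
        if self.lib_sizes is None:
            self.lib_sizes = self.values.sum(axis=0).astype(float)
        if self.full_lengths is None:
            self.full_lengths = self.gene_lengths.copy()

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def cpm(self) -> pd.DataFrame:
        """Counts per million, computed against ``lib_sizes``."""
        return self.values.div(self.lib_sizes, axis=1) * 1e6

    def with_values(self, values: pd.DataFrame) -> "CountMatrix":
        """Copy of this matrix carrying new values but the same metadata."""
        return CountMatrix(
            values=values,
            gene_lengths=self.gene_lengths.loc[values.index].copy(),
            full_lengths=self.full_lengths.loc[values.index].copy(),
            sample_info=None if self.sample_info is None else self.sample_info.copy(),
            lib_sizes=self.lib_sizes.copy(),
        )
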