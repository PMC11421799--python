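"""Pooling, read-level subsampling and saturation curves.

Higher coverage is simulated by pooling reads from several libraries and
subsampling the pool to a ladder of depths; peaks are re-called at each depth
and the per-depth and cumulative-unique peak counts form the saturation
curve.  Subsampling draws reads without replacement (multivariate
hypergeometric over the per-position read multiset), and the mock pool is
subsampled to the same fraction so CMC/mock Z ratios stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .peaks import CallThresholds, scan_transcriptome
from .tracks import EndCountTrack, GenomeSequence, TranscriptModel, STRANDS


@dataclass
class SaturationCurve:
    depths: list[int]
    peaks_at_depth: list[int]
    cumulative_unique: list[int]
    seed: int
    sites_by_depth: list[set[tuple[int, str]]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth": self.depths,
            "peaks_at_depth": self.peaks_at_depth,
            "cumulative_unique": self.cumulative_unique,
        })


def pool_tracks(tracks: Sequence[EndCountTrack], label: str = "pool") -> EndCountTrack:
    """Sum per-position counts (and total reads) across libraries."""
    if not tracks:
        raise ValueError("nothing to pool")
    length = tracks[0].length
    if any(t.length != length for t in tracks):
        raise ValueError("cannot pool tracks over different genomes")
    counts = {
        s: np.sum([t.counts[s] for t in tracks], axis=0) for s in STRANDS
    }
    total = sum(t.total_reads for t in tracks)
    return EndCountTrack(length, library_label=label, counts=counts, total_reads=total)


def subsample(track: EndCountTrack, depth: int, seed: int) -> EndCountTrack:
    """Draw exactly ``depth`` reads without replacement from a track.

    Each mapped read is one (position, strand) record; the draw is a
    multivariate hypergeometric sample over the per-position counts, so
    expected counts scale by ``depth / total`` and the result is deterministic
    given ``seed``.
    """
    available = track.positional_sum()
    if depth > available:
        raise ValueError(f"requested depth {depth} exceeds {available} reads")
    rng = np.random.default_rng(seed)
    colors = np.concatenate([track.counts[s] for s in STRANDS])
    if depth == available:
        drawn = colors
    else:
        drawn = rng.multivariate_hypergeometric(colors, depth, method="marginals")
    n = track.length
    counts = {"+": drawn[:n].astype(np.int64), "-": drawn[n:].astype(np.int64)}
    return EndCountTrack(
        track.length, library_label=f"{track.library_label}@{depth}",
        counts=counts, total_reads=depth,
    )


def saturation_curve(
    pool: EndCountTrack,
    depths: Sequence[int],
    mock_pool: EndCountTrack,
    genome: GenomeSequence,
    models: Sequence[TranscriptModel],
    thresholds: CallThresholds = CallThresholds(),
    seed: int = 0,
    window_len: int = 100,
) -> SaturationCurve:
    """Call peaks along a ladder of subsample depths (one draw per depth).

    ``depths`` must be sorted ascending and bounded by the pool size; the mock
    pool is subsampled to the matching fraction of its own reads.  Cumulative
    unique counts accumulate distinct (position, strand) calls across depths.
    """
    depths = [int(d) for d in depths]
    if depths != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    pool_total = pool.positional_sum()
    mock_total = mock_pool.positional_sum()
    if depths and depths[-1] > pool_total:
        raise ValueError("deepest subsample exceeds the pooled reads")
    peaks_at_depth: list[int] = []
    sites_by_depth: list[set[tuple[int, str]]] = []
    cumulative: set[tuple[int, str]] = set()
    cumulative_unique: list[int] = []
    for i, depth in enumerate(depths):
        sub = subsample(pool, depth, seed=seed * 100_003 + i)
        mock_depth = min(mock_total, int(round(mock_total * depth / pool_total)))
        mock_sub = subsample(mock_pool, mock_depth, seed=seed * 100_003 + 50_000 + i)
        calls = scan_transcriptome(
            {"WT-CMC": sub, "WT-mock": mock_sub}, genome, models,
            thresholds=thresholds, window_len=window_len,
        )
        called = {(c.position, c.strand) for c in calls if c.status == "called"}
        peaks_at_depth.append(len(called))
        sites_by_depth.append(called)
        cumulative |= called
        cumulative_unique.append(len(cumulative))
    return SaturationCurve(
        depths=depths, peaks_at_depth=peaks_at_depth,
        cumulative_unique=cumulative_unique, seed=seed,
        sites_by_depth=sites_by_depth,
    )
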