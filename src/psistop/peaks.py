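"""Winsorized-Z peak calling for CMC reverse-transcription-stop pileups.

The statistic: for each uridine, the read-5'-end count immediately downstream
of the U (the RT-stop position, U+1 in transcript orientation) is compared to
a 100-nt background window surrounding it.  The background is 95%-winsorized
(values above the 95th percentile are capped at it; the target itself is
never altered), and

    z = (count[target] - mean(winsorized background)) / sd(winsorized background)

with a population (divide-by-n) standard deviation.  A site is CMC-dependent
when the CMC-treated Z >= 15 and is at least 3-fold the mock-treated Z, with
at least 100 reads mapping to each window.

Background windows near transcript boundaries are shifted to keep clear of
end pileups: the window's 5' boundary must sit >= 40 nt downstream of the
nearest upstream transcript 5' end and >= 5 nt downstream of the nearest
upstream 3' end; the window's 3' boundary must sit >= 25 nt upstream of the
nearest downstream 3' end and >= 5 nt upstream of the nearest downstream
5' end.  Windows that cannot satisfy all four constraints are infeasible and
the site is reported as insufficiently covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .tracks import (
    EndCountTrack,
    GenomeSequence,
    SiteCall,
    TranscriptModel,
    containing_transcript,
    deorient,
    orient,
)

# End-distance constraints for background-window placement (nt).
MIN_FROM_UPSTREAM_5P = 40
MIN_FROM_UPSTREAM_3P = 5
MIN_FROM_DOWNSTREAM_3P = 25
MIN_FROM_DOWNSTREAM_5P = 5


class WindowInfeasibleError(ValueError):
    """No background-window placement satisfies the end-distance constraints."""


@dataclass(frozen=True)
class CallThresholds:
    """Decision-rule thresholds for site calling and enzyme assignment."""

    z_min: float = 15.0
    mock_fold: float = 3.0
    coverage_min: int = 100
    ko_z_max: float = 10.0
    ko_fold: float = 4.0

    def __post_init__(self) -> None:
        for name in ("z_min", "mock_fold", "coverage_min", "ko_z_max", "ko_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class WindowSpec:
    """A contiguous background window around a target position.

    ``start``/``end`` bound the full genomic half-open interval, which contains
    the target plus ``window_len`` background positions; the target itself is
    excluded from the background.
    """

    target: int
    strand: str
    start: int
    end: int
    shifted: bool

    @property
    def window_len(self) -> int:
        return self.end - self.start - 1

    def background_positions(self) -> np.ndarray:
        pos = np.arange(self.start, self.end)
        return pos[pos != self.target]


@dataclass(frozen=True)
class ZResult:
    z: float | None
    window_reads: int
    covered: bool
    p95: float | None = None
    reason: str | None = None


def winsorize(
    values: Sequence[float], pct: float = 95.0, method: str = "linear"
) -> np.ndarray:
    """Cap values above the ``pct``-th percentile at that percentile.

    Values at or below the percentile are unchanged; output length equals
    input length.  (This one-sided capping is the operation needed here; it
    is not the symmetric fixed-fraction trimming some statistics libraries
    call winsorization.)

    ``method`` selects the percentile definition (any numpy percentile
    method).  The default interpolates linearly between order statistics;
    note that re-winsorizing is then not exactly idempotent, because capping
    lowers the interpolated percentile of the capped list.  With
    ``method="lower"`` the cap is itself an order statistic and the
    operation is exactly idempotent.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot winsorize an empty window")
    cap = float(np.percentile(v, pct, method=method))
    return np.minimum(v, cap)


def adjust_background_window(
    target: int,
    strand: str,
    models: Iterable[TranscriptModel],
    window_len: int = 100,
    genome_length: int | None = None,
) -> WindowSpec:
    """Place a ``window_len``-background window around ``target``.

    The window is kept as close to centered as possible subject to the four
    transcript-end distance constraints (module docstring); the smallest
    displacement wins, ties broken toward the transcript 3' direction.
    Ends are classified upstream/downstream relative to the target in
    transcript orientation.

    Raises
    ------
    WindowInfeasibleError
        if no placement containing the target satisfies every constraint.
    """
    t = orient(target, strand)
    lo = t - window_len  # window interval is window_len + 1 oriented positions
    hi = t
    if genome_length is not None:
        # keep the genomic interval inside [0, genome_length)
        if strand == "+":
            lo = max(lo, 0)
            hi = min(hi, genome_length - 1 - window_len)
        else:
            lo = max(lo, -(genome_length - 1))
            hi = min(hi, -window_len)

    for m in models:
        if m.strand != strand:
            continue
        for e in m.five_prime_ends:
            oe = orient(e, strand)
            if oe <= t:
                lo = max(lo, oe + MIN_FROM_UPSTREAM_5P)
            else:
                hi = min(hi, oe - MIN_FROM_DOWNSTREAM_5P - window_len)
        for e in m.three_prime_ends:
            oe = orient(e, strand)
            if oe <= t:
                lo = max(lo, oe + MIN_FROM_UPSTREAM_3P)
            else:
                hi = min(hi, oe - MIN_FROM_DOWNSTREAM_3P - window_len)

    if lo > hi:
        raise WindowInfeasibleError(
            f"no feasible {window_len}-nt window for target {target} ({strand})"
        )
    centered = t - window_len // 2
    # nearest feasible start; on a tie (cannot happen for an interval, but the
    # preference is documented) shift toward 3', i.e. the larger oriented start
    s = min(max(centered, lo), hi)
    shifted = s != centered
    g1 = deorient(s, strand)
    g2 = deorient(s + window_len, strand)
    start, end = min(g1, g2), max(g1, g2) + 1
    return WindowSpec(target=target, strand=strand, start=start, end=end, shifted=shifted)


def compute_z(
    track: EndCountTrack,
    window: WindowSpec,
    thresholds: CallThresholds = CallThresholds(),
    pct: float = 95.0,
) -> ZResult:
    """Winsorized Z-score of the target against its background window.

    ``window_reads`` sums counts over background plus target; windows with
    fewer than ``coverage_min`` reads are uncovered and yield no Z.  A
    zero-dispersion background leaves the Z undefined (reason
    ``degenerate-background``) rather than manufacturing an infinite score.
    """
    counts = track.counts[window.strand][window.start:window.end].astype(float)
    window_reads = int(counts.sum())
    if window_reads < thresholds.coverage_min:
        return ZResult(z=None, window_reads=window_reads, covered=False,
                       reason="low-coverage")
    idx = window.target - window.start
    target_count = counts[idx]
    background = np.delete(counts, idx)
    wins = winsorize(background, pct)
    cap = float(np.percentile(background, pct))
    mu = float(wins.mean())
    sd = float(wins.std(ddof=0))
    if sd == 0.0:
        return ZResult(z=None, window_reads=window_reads, covered=True,
                       p95=cap, reason="degenerate-background")
    return ZResult(z=(target_count - mu) / sd, window_reads=window_reads,
                   covered=True, p95=cap)


def call_cmc_dependent(
    cmc: ZResult, mock: ZResult, thresholds: CallThresholds = CallThresholds()
) -> str:
    """Apply the CMC-dependence rule: Z >= z_min and >= mock_fold x mock Z.

    Returns ``called``, ``not_called`` or ``insufficient``.  A mock Z <= 0
    satisfies the fold condition trivially.  An undefined Z in a covered
    window (degenerate background) leaves the site insufficient.
    """
    if not (cmc.covered and mock.covered):
        return "insufficient"
    if cmc.z is None or mock.z is None:
        return "insufficient"
    if cmc.z < thresholds.z_min:
        return "not_called"
    if mock.z > 0 and cmc.z < thresholds.mock_fold * mock.z:
        return "not_called"
    return "called"


def peak_position(u_position: int, strand: str) -> int:
    """RT stops place the read 5' end immediately downstream of the modified U."""
    return deorient(orient(u_position, strand) + 1, strand)


def site_position(peak: int, strand: str) -> int:
    """Inverse of :func:`peak_position`: report the modified U, not U+1."""
    return deorient(orient(peak, strand) - 1, strand)


def scan_transcriptome(
    tracks: Mapping[str, EndCountTrack],
    genome: GenomeSequence,
    models: Sequence[TranscriptModel],
    thresholds: CallThresholds = CallThresholds(),
    window_len: int = 100,
    cmc_label: str = "WT-CMC",
    mock_label: str = "WT-mock",
    extra_labels: Sequence[str] = (),
) -> list[SiteCall]:
    """Score every uridine inside annotated genes and call CMC-dependent sites.

    ``tracks`` must contain ``cmc_label`` and ``mock_label``; ``extra_labels``
    (e.g. knockout libraries) are scored at positions where the CMC window is
    covered, so downstream enzyme assignment can reuse the records.  The peak
    (RT-stop) position scored for a U at position ``u`` is ``u + 1`` in
    transcript orientation; results are reported at the U itself.
    """
    if cmc_label not in tracks:
        raise KeyError(f"missing CMC track {cmc_label!r}")
    if mock_label not in tracks:
        raise KeyError(f"missing mock track {mock_label!r}")
    cmc_track = tracks[cmc_label]
    mock_track = tracks[mock_label]
    L = len(genome)
    calls: list[SiteCall] = []
    seq = genome.sequence
    for m in models:
        base_wanted = "T" if m.strand == "+" else "A"
        for pos in range(m.start, m.end):
            if seq[pos] != base_wanted:
                continue
            peak = peak_position(pos, m.strand)
            if not (0 <= peak < L):
                continue
            call = SiteCall(position=pos, strand=m.strand, gene_id=m.gene_id)
            try:
                window = adjust_background_window(
                    peak, m.strand, models, window_len, genome_length=L
                )
            except WindowInfeasibleError:
                call.status = "insufficient"
                call.covered_by_library[cmc_label] = False
                calls.append(call)
                continue
            zc = compute_z(cmc_track, window, thresholds)
            call.z_by_library[cmc_label] = zc.z
            call.covered_by_library[cmc_label] = zc.covered
            if not zc.covered:
                call.status = "insufficient"
                calls.append(call)
                continue
            zm = compute_z(mock_track, window, thresholds)
            call.z_by_library[mock_label] = zm.z
            call.covered_by_library[mock_label] = zm.covered
            status = call_cmc_dependent(zc, zm, thresholds)
            call.status = status
            if status == "called":
                for lab in extra_labels:
                    zk = compute_z(tracks[lab], window, thresholds)
                    call.z_by_library[lab] = zk.z
                    call.covered_by_library[lab] = zk.covered
            calls.append(call)
    return calls


def zresult_from_call(call: SiteCall, label: str) -> ZResult:
    """Reconstruct the (z, covered) pair a scan recorded for one library."""
    return ZResult(
        z=call.z_by_library.get(label),
        window_reads=0,
        covered=call.covered_by_library.get(label, False),
    )
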