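import numpy as np
import pytest

import psistop as ps


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study: 6 transcripts, 3 planted sites, 2 knockouts."""
    cfg = ps.SimulationConfig(
        n_transcripts=6, transcript_length=800, depth=200_000,
        expression_sigma=0.4,
        planted_sites=[
            ps.PlantedSite("gene000", 400, enzyme="rluA"),
            ps.PlantedSite("gene002", 250, enzyme="rluD"),
            ps.PlantedSite("gene004", 600, enzyme="rluA"),
        ],
        seed=11,
    )
    tr = ps.make_transcriptome(cfg)
    tracks = ps.simulate_pseudoseq_suite(cfg, tr, knockouts=["rluA", "rluD"])
    return cfg, tr, tracks


@pytest.fixture()
def flat_model():
    """A long unannotated-interior gene: end constraints inactive mid-gene."""
    return ps.TranscriptModel(gene_id="flat", strand="+", start=0, end=2400)


def brute_force_z(counts, target_idx, pct=95.0, coverage_min=100):
    """Independent winsorized-Z oracle: sort-based percentile, explicit mean/sd.

    Returns (z, window_reads, covered); z is None when uncovered or the
    background has no dispersion.
    """
    import math

    counts = [float(c) for c in counts]
    window_reads = sum(counts)
    if window_reads < coverage_min:
        return None, window_reads, False
    bg = [c for i, c in enumerate(counts) if i != target_idx]
    s = sorted(bg)
    k = (len(s) - 1) * pct / 100.0
    f, c = math.floor(k), math.ceil(k)
    p95 = s[f] + (k - f) * (s[c] - s[f])
    wins = [min(v, p95) for v in bg]
    mu = sum(wins) / len(wins)
    var = sum((v - mu) ** 2 for v in wins) / len(wins)
    sd = math.sqrt(var)
    if sd == 0:
        return None, window_reads, True
    return (counts[target_idx] - mu) / sd, window_reads, True


@pytest.fixture(scope="session")
def z_oracle():
    return brute_force_z


def make_track_window(counts, start=1000, strand="+", length=4000):
    """Wrap raw window counts into a track + WindowSpec with target centered."""
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.size
    track = ps.EndCountTrack(length)
    track.counts[strand][start:start + n] = counts
    track.total_reads = track.positional_sum()
    target = start + n // 2
    spec = ps.WindowSpec(target=target, strand=strand, start=start,
                         end=start + n, shifted=False)
    return track, spec, n // 2


@pytest.fixture(scope="session")
def window_factory():
    return make_track_window
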