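"""Synthetic Pseudo-Seq and BID-seq library generator with planted ground truth.

Emulates the statistical structure of CMC reverse-transcription-stop data:
each sequenced fragment starts at a uniform position on a transcript and the
reverse transcriptase walks 5'-ward; in CMC-treated libraries it is blocked
one nucleotide downstream of a modified U with probability
``stop_efficiency x stoichiometry``, elsewhere it terminates at a small
per-position background rate, otherwise it runs through to the transcript 5'
end (producing the end pileup real libraries show; ``end_pileup_weight`` adds
extra mass there).  Mock libraries ignore the planted sites; a knockout
library ignores the sites of one synthase.

Everything is deterministic given the seed, and the total simulated read
count equals the configured depth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import EndCountTrack, GenomeSequence, TranscriptModel

#: The 11 E. coli pseudouridine synthases.
ENZYMES = (
    "rluA", "rluB", "rluC", "rluD", "rluE", "rluF",
    "rsuA", "truA", "truB", "truC", "truD",
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSite:
    """A modified uridine planted in the synthetic transcriptome.

    ``u_position`` is transcript-local (0-based from the transcript 5' end)
    when used in a :class:`SimulationConfig`; the generated truth table also
    reports genomic coordinates.
    """

    gene_id: str
    u_position: int
    enzyme: str = "rluA"
    stop_efficiency: float = 0.9
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        if self.enzyme != "none" and self.enzyme not in ENZYMES:
            raise ConfigError(f"unknown enzyme {self.enzyme!r}")
        for name in ("stop_efficiency", "stoichiometry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

    @property
    def effective_truncation(self) -> float:
        return self.stop_efficiency * self.stoichiometry


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a small bacterial-like transcriptome: 20 transcripts of
    1 kb, log-normal expression (sigma controls the dynamic range; sigma=1
    spans roughly two orders of magnitude), a per-position background RT-stop
    rate of 1e-3, a 2% extra 5'-end pileup, and 400k reads per library.
    """

    n_transcripts: int = 20
    transcript_length: int = 1000
    expression_mu: float = 0.0
    expression_sigma: float = 1.0
    planted_sites: list[PlantedSite] = field(default_factory=list)
    background_stop_rate: float = 1e-3
    end_pileup_weight: float = 0.02
    depth: int = 400_000
    intergenic_gap: int = 200
    minus_strand_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        for name in ("background_stop_rate", "end_pileup_weight",
                     "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")


@dataclass
class Transcriptome:
    """Generated genome + annotation + expression, with planted-site truth."""

    genome: GenomeSequence
    models: list[TranscriptModel]
    expression: dict[str, float]
    sites: list[PlantedSite]  # transcript-local coordinates

    def model(self, gene_id: str) -> TranscriptModel:
        for m in self.models:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)

    def genomic_site(self, site: PlantedSite) -> tuple[int, str]:
        m = self.model(site.gene_id)
        return m.to_genomic_pos(site.u_position), m.strand

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            g, strand = self.genomic_site(s)
            rows.append({
                "gene_id": s.gene_id, "u_position": g, "strand": strand,
                "transcript_u_position": s.u_position, "enzyme": s.enzyme,
                "stop_efficiency": s.stop_efficiency,
                "stoichiometry": s.stoichiometry,
            })
        return pd.DataFrame(rows)


_BASES = np.array(list("ACGT"))


def make_transcriptome(config: SimulationConfig) -> Transcriptome:
    """Generate random transcript sequences with a UURAA motif at each planted site.

    The motif is written so that the planted U is its first position (DNA
    ``TTRAA`` on the coding strand).  Transcripts are laid head-to-tail on a
    single synthetic chromosome separated by intergenic gaps; a configurable
    fraction goes on the minus strand.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.transcript_length
    gap = config.intergenic_gap
    n = config.n_transcripts
    genome_len = gap + n * (L + gap)
    seq = rng.choice(_BASES, size=genome_len)

    models: list[TranscriptModel] = []
    expression: dict[str, float] = {}
    sites_by_gene: dict[str, list[PlantedSite]] = {}
    for s in config.planted_sites:
        if not 0 <= s.u_position < L - 5:
            raise ConfigError(
                f"site at transcript position {s.u_position} outside transcript"
            )
        sites_by_gene.setdefault(s.gene_id, []).append(s)

    levels = rng.lognormal(config.expression_mu, config.expression_sigma, size=n)
    strands = np.where(
        rng.random(n) < config.minus_strand_fraction, "-", "+"
    )
    from Bio.Seq import Seq

    for i in range(n):
        gid = f"gene{i:03d}"
        start = gap + i * (L + gap)
        end = start + L
        strand = str(strands[i])
        cds_len = (L // 3) * 3 - 6  # leave short UTRs, frame starts at +3
        cds_start = start + 3 if strand == "+" else end - 3 - cds_len
        models.append(TranscriptModel(
            gene_id=gid, strand=strand, start=start, end=end,
            cds_start=cds_start, cds_end=cds_start + cds_len,
        ))
        expression[gid] = float(levels[i])
        for s in sites_by_gene.get(gid, []):
            # plant TT[AG]AA so the site's U is motif position 1
            r = "A" if rng.random() < 0.5 else "G"
            motif = "TT" + r + "AA"
            m = models[-1]
            g0 = m.to_genomic_pos(s.u_position)
            if strand == "+":
                seq[g0:g0 + 5] = list(motif)
            else:
                rc = str(Seq(motif).reverse_complement())
                seq[g0 - 4:g0 + 1] = list(rc)
    unknown = set(sites_by_gene) - set(expression)
    if unknown:
        raise ConfigError(f"planted sites reference unknown genes: {sorted(unknown)}")
    genome = GenomeSequence("synthetic", "".join(seq))
    return Transcriptome(genome, models, expression, list(config.planted_sites))


def simulate_library(
    config: SimulationConfig,
    transcriptome: Transcriptome,
    condition: str = "CMC",
    knockout: str | None = None,
    seed: int | None = None,
    label: str | None = None,
) -> EndCountTrack:
    """Simulate one library's 5'-end count track.

    ``condition`` is ``CMC`` or ``mock``; ``knockout`` names a synthase whose
    sites lose their CMC truncation signal.  Reads are drawn per transcript
    proportional to expression; each read's 3' start is uniform on the
    transcript and its 5' end is the first stop encountered walking 5'-ward.
    """
    if condition not in ("CMC", "mock"):
        raise ConfigError(f"condition must be CMC or mock, got {condition!r}")
    if knockout is not None and knockout != "none" and knockout not in ENZYMES:
        raise ConfigError(f"unknown enzyme {knockout!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    models = transcriptome.models
    gene_ids = [m.gene_id for m in models]
    weights = np.array([transcriptome.expression[g] for g in gene_ids])
    probs = weights / weights.sum()
    L = config.transcript_length
    depth = config.depth

    # reads per transcript (multinomial keeps the total exactly at depth)
    per_gene = rng.multinomial(depth, probs)

    if label is None:
        ko = f"d{knockout}-" if knockout not in (None, "none") else ""
        label = f"{ko}WT-{condition}" if not ko else f"{ko}{condition}"
    track = EndCountTrack(len(transcriptome.genome), library_label=label)
    bg = config.background_stop_rate

    for m, n_reads in zip(models, per_gene):
        if n_reads == 0:
            continue
        active = [
            s for s in transcriptome.sites
            if s.gene_id == m.gene_id and condition == "CMC"
            and s.enzyme != (knockout or "none")
        ]
        p3 = rng.integers(0, L, size=n_reads)  # transcript-local 3' start
        # background stop: first success walking 5'-ward from p3 (distance >= 0)
        if bg > 0:
            g = rng.geometric(bg, size=n_reads) - 1  # distance of first stop
            stop_pos = p3 - g
        else:
            stop_pos = np.full(n_reads, -1)
        stop_pos = np.maximum(stop_pos, 0)  # run-through ends at the 5' end
        # planted-site truncation: read blocked at u+1 when it covers the site
        for s in active:
            tstop = s.u_position + 1
            reach = p3 >= tstop
            hit = reach & (rng.random(n_reads) < s.effective_truncation)
            # the RT meets the planted block before any background stop
            # further 5'; the larger transcript coordinate wins the walk
            stop_pos = np.where(hit & (tstop >= stop_pos), tstop, stop_pos)
        # extra transcript-5'-end pileup mass
        if config.end_pileup_weight > 0:
            at_end = rng.random(n_reads) < config.end_pileup_weight
            stop_pos = np.where(at_end, 0, stop_pos)
        genomic = (
            m.start + stop_pos if m.strand == "+" else m.end - 1 - stop_pos
        )
        np.add.at(track.counts[m.strand], genomic, 1)
    track.total_reads = depth
    return track


def simulate_pseudoseq_suite(
    config: SimulationConfig,
    transcriptome: Transcriptome,
    knockouts: Sequence[str] = (),
    seed: int | None = None,
) -> dict[str, EndCountTrack]:
    """WT-CMC + WT-mock (+ one CMC library per requested knockout)."""
    base = config.seed if seed is None else seed
    tracks = {
        "WT-CMC": simulate_library(config, transcriptome, "CMC", None,
                                   seed=base, label="WT-CMC"),
        "WT-mock": simulate_library(config, transcriptome, "mock", None,
                                    seed=base + 1, label="WT-mock"),
    }
    for i, enz in enumerate(knockouts):
        tracks[f"d{enz}-CMC"] = simulate_library(
            config, transcriptome, "CMC", enz, seed=base + 2 + i,
            label=f"d{enz}-CMC",
        )
    return tracks


def simulate_bidseq_pileup(
    sites: Sequence[int],
    stoichiometry: Mapping[int, float],
    depth: int,
    seed: int = 0,
    length: int | None = None,
    error_rate: float = 2e-3,
    deletion_rate_at_full_mod: float = 0.9,
) -> pd.DataFrame:
    """Simulate a targeted bisulfite-sequencing deletion pileup.

    At each modified site, deletion events occur with probability
    ``deletion_rate_at_full_mod x stoichiometry``; each event is 1 or 2 nt
    long with equal odds and is counted at its 5'-most position (the site).
    Elsewhere deletions occur at ``error_rate``.  Returns a tidy table with
    columns ``position``, ``depth``, ``deletions``.
    """
    if depth <= 0:
        raise ConfigError("depth must be positive")
    if not 0.0 <= deletion_rate_at_full_mod <= 1.0:
        raise ConfigError("deletion_rate_at_full_mod must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if length is None:
        length = (max(sites) + 10) if sites else 100
    rates = np.full(length, error_rate)
    for s in sites:
        st = stoichiometry.get(s, 0.0)
        if not 0.0 <= st <= 1.0:
            raise ConfigError(f"stoichiometry at {s} must be in [0, 1]")
        rates[s] = min(1.0, error_rate + deletion_rate_at_full_mod * st)
    deletions = rng.binomial(depth, rates)
    # deletion length (1 or 2 nt, equal odds) does not move the anchored count
    return pd.DataFrame({
        "position": np.arange(length),
        "depth": np.full(length, depth),
        "deletions": deletions,
    })
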