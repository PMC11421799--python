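"""Sequence-context annotation of pseudouridine sites.

Covers the RluA recognition-motif classes (UURAA / UURBA / UUYAA, classified
on the RNA 5-mer whose first base is the modified U), position-frequency
matrices around sites, codon and amino-acid context within CDS, and the
expression- and motif-matched background-site selection used to contrast
modified against unmodified UURAA instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .tracks import (
    GenomeSequence,
    TranscriptModel,
    containing_transcript,
    orient,
)

RNA_BASES = ("A", "C", "G", "U")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}
NOT_A = {"C", "G", "U"}

MOTIF_CLASSES = ("UURAA", "UURBA", "UUYAA", "other")


def classify_5mer(kmer: str) -> str:
    """Classify an RNA 5-mer into {UURAA, UURBA, UUYAA, other}.

    The classes are mutually exclusive: R (purine) and Y (pyrimidine) are
    disjoint at position 3, and A and B (not A) are disjoint at position 4,
    so each 5-mer matches at most one pattern.
    """
    k = kmer.upper().replace("T", "U")
    if len(k) != 5:
        raise ValueError(f"need a 5-mer, got {kmer!r}")
    if not set(k) <= set(RNA_BASES):
        raise ValueError(f"non-RNA characters in {kmer!r}")
    if k[0] == "U" and k[1] == "U" and k[4] == "A":
        if k[2] in PURINES and k[3] == "A":
            return "UURAA"
        if k[2] in PURINES and k[3] in NOT_A:
            return "UURBA"
        if k[2] in PYRIMIDINES and k[3] == "A":
            return "UUYAA"
    return "other"


def site_5mer(genome: GenomeSequence, site: int, strand: str) -> str:
    """Strand-aware RNA 5-mer starting at the site U (site = position 1)."""
    if strand == "+":
        dna = genome.subseq(site, site + 5, "+")
    else:
        dna = genome.subseq(site - 4, site + 1, "-")
    return dna.replace("T", "U")


def classify_motif(genome: GenomeSequence, site: int, strand: str) -> str:
    """Motif class of the 5-mer beginning at a (putative Psi) site."""
    return classify_5mer(site_5mer(genome, site, strand))


def position_frequency(
    sites: Iterable[tuple[int, str]],
    genome: GenomeSequence,
    flank: int = 5,
) -> pd.DataFrame:
    """Base counts per offset around a set of sites (offset 0 = the site U).

    Returns a DataFrame indexed by offset (-flank..+flank) with one column per
    RNA base; every column sum equals the number of sites.
    """
    sites = list(sites)
    offsets = range(-flank, flank + 1)
    counts = {b: np.zeros(2 * flank + 1, dtype=int) for b in RNA_BASES}
    for pos, strand in sites:
        if strand == "+":
            dna = genome.subseq(pos - flank, pos + flank + 1, "+")
        else:
            dna = genome.subseq(pos - flank, pos + flank + 1, "-")
        rna = dna.replace("T", "U")
        for i, b in enumerate(rna):
            counts[b][i] += 1
    df = pd.DataFrame(counts, index=pd.Index(list(offsets), name="offset"))
    return df


@dataclass(frozen=True)
class CodonContext:
    codon: str  # RNA 3-mer
    amino_acid: str  # single letter, '*' for stop
    codon_index: int  # 1-based codon number within the CDS
    position_in_codon: int  # 1, 2 or 3

    @property
    def is_stop(self) -> bool:
        return self.amino_acid == "*"


def codon_context(
    site: int, model: TranscriptModel, genome: GenomeSequence
) -> CodonContext | None:
    """Codon/amino-acid context of a site within its CDS (None for UTR sites)."""
    if model.cds_start is None or model.cds_end is None:
        return None
    if not (model.cds_start <= site < model.cds_end):
        return None
    if model.strand == "+":
        offset = site - model.cds_start
        codon_start = model.cds_start + (offset // 3) * 3
        dna = genome.subseq(codon_start, codon_start + 3, "+")
    else:
        offset = model.cds_end - 1 - site
        codon_end = model.cds_end - (offset // 3) * 3
        dna = genome.subseq(codon_end - 3, codon_end, "-")
    aa = str(Seq(dna).translate())
    return CodonContext(
        codon=dna.replace("T", "U"),
        amino_acid=aa,
        codon_index=offset // 3 + 1,
        position_in_codon=offset % 3 + 1,
    )


def amino_acid_fractions(
    sites: Iterable[tuple[int, str]],
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
) -> pd.Series:
    """Fraction of CDS-internal sites per encoded amino acid."""
    counts: dict[str, int] = {}
    n = 0
    for pos, strand in sites:
        m = containing_transcript(models, pos, strand)
        if m is None:
            continue
        ctx = codon_context(pos, m, genome)
        if ctx is None:
            continue
        counts[ctx.amino_acid] = counts.get(ctx.amino_acid, 0) + 1
        n += 1
    if n == 0:
        return pd.Series(dtype=float)
    return pd.Series(counts).sort_values(ascending=False) / n


def scan_motif_sites(
    genome: GenomeSequence, model: TranscriptModel, motif_class: str = "UURAA"
) -> list[int]:
    """All positions within a gene whose 5-mer matches the given class."""
    hits = []
    for pos in range(model.start, model.end):
        lo, hi = (pos, pos + 5) if model.strand == "+" else (pos - 4, pos + 1)
        if lo < 0 or hi > len(genome):
            continue
        if classify_motif(genome, pos, model.strand) == motif_class:
            hits.append(pos)
    return hits


def select_background(
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
    psi_sites: Iterable[tuple[int, str]],
    rpkm_min: float = 105.0,
    motif_class: str = "UURAA",
    exclusion_nt: int = 100,
    n_max: int | None = None,
    seed: int = 0,
) -> list[tuple[int, str]]:
    """Expression-matched unmodified motif sites for structural comparisons.

    Keeps every first-U position of a ``motif_class`` instance inside genes
    with RPKM >= ``rpkm_min`` (the models' ``rpkm`` attribute), then removes
    any candidate within ``exclusion_nt`` of a called Psi site on the same
    strand.  With ``n_max`` set, a deterministic uniform sample is drawn.
    """
    psi = list(psi_sites)
    out: list[tuple[int, str]] = []
    for m in models:
        if m.rpkm < rpkm_min:
            continue
        for pos in scan_motif_sites(genome, m, motif_class):
            near_psi = any(
                strand == m.strand and abs(pos - p) <= exclusion_nt
                for p, strand in psi
            )
            if not near_psi:
                out.append((pos, m.strand))
    out.sort()
    if n_max is not None and len(out) > n_max:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(out), size=n_max, replace=False))
        out = [out[i] for i in idx]
    return out
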