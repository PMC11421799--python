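"""Data model and I/O for genomes, annotations, 5'-end count tracks and result tables.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open.  bedGraph and BED writers
emit 0-based half-open intervals; the wiggle (variableStep) writer emits
1-based positions per the wiggle standard.  Conversion happens only at I/O.

Strand conventions
------------------
"Downstream" always means the transcript 3' direction: increasing genomic
coordinate on the plus strand, decreasing on the minus strand.  The helper
:func:`orient` maps genomic positions to strand-oriented positions so that
downstream is always increasing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

STRANDS = ("+", "-")
_DNA = set("ACGT")


class TrackParseError(ValueError):
    """A track file line failed to parse; the message includes the line number."""


class TrackValidationError(ValueError):
    """Track content violates an invariant (e.g. negative counts)."""


def orient(position: int, strand: str) -> int:
    """Map a genomic position to a strand-oriented axis where downstream is +1."""
    if strand == "+":
        return position
    if strand == "-":
        return -position
    raise ValueError(f"unknown strand {strand!r}")


def deorient(opos: int, strand: str) -> int:
    return opos if strand == "+" else -opos


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence.upper()) - _DNA
        if bad:
            raise ValueError(f"non-ACGT characters in genome: {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int, strand: str = "+") -> str:
        """Strand-aware base (coding-strand identity) at a genomic position."""
        b = self.sequence[position]
        if strand == "-":
            b = str(Seq(b).reverse_complement())
        return b

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """Strand-aware subsequence of genomic half-open interval [start, end)."""
        if start < 0 or end > len(self):
            raise IndexError(f"[{start}, {end}) outside genome of length {len(self)}")
        s = self.sequence[start:end]
        if strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def is_u(self, position: int, strand: str) -> bool:
        """True if the coding-strand base at ``position`` is a U (T in DNA)."""
        return self.base(position, strand) == "T"

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(self.name, str(Seq(self.sequence).reverse_complement()))


class EndCountTrack:
    """Per-position, per-strand counts of read 5' ends.

    Parameters
    ----------
    length:
        Genome length; defines the valid coordinate range ``[0, length)``.
    library_label:
        Free-text label, e.g. ``WT-CMC``, ``WT-mock``, ``rluA-CMC``.
    total_reads:
        Total mapped reads in the library.  Defaults to the sum of counts;
        may exceed it when reads map outside the tracked positions
        (e.g. rRNA/tRNA reads excluded from the track).
    """

    def __init__(
        self,
        length: int,
        library_label: str = "",
        counts: Mapping[str, np.ndarray] | None = None,
        total_reads: int | None = None,
    ) -> None:
        if length <= 0:
            raise ValueError("track length must be positive")
        self.length = int(length)
        self.library_label = library_label
        if counts is None:
            self.counts = {s: np.zeros(length, dtype=np.int64) for s in STRANDS}
        else:
            self.counts = {}
            for s in STRANDS:
                arr = np.asarray(counts.get(s, np.zeros(length)), dtype=np.int64)
                if arr.shape != (length,):
                    raise TrackValidationError(f"strand {s} counts have wrong length")
                if (arr < 0).any():
                    raise TrackValidationError(f"negative counts on strand {s}")
                self.counts[s] = arr.copy()
        ssum = int(sum(int(self.counts[s].sum()) for s in STRANDS))
        self.total_reads = ssum if total_reads is None else int(total_reads)
        if self.total_reads < ssum:
            raise TrackValidationError(
                f"total_reads ({self.total_reads}) < sum of positional counts ({ssum})"
            )

    # -- basic accessors -------------------------------------------------
    def positional_sum(self) -> int:
        return int(sum(int(self.counts[s].sum()) for s in STRANDS))

    def window_sum(self, start: int, end: int, strand: str) -> int:
        return int(self.counts[strand][start:end].sum())

    def add_count(self, position: int, strand: str, n: int = 1) -> None:
        self.counts[strand][position] += n
        self.total_reads += n

    def copy(self) -> "EndCountTrack":
        return EndCountTrack(
            self.length, self.library_label,
            {s: self.counts[s] for s in STRANDS}, self.total_reads,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EndCountTrack):
            return NotImplemented
        return (
            self.length == other.length
            and self.total_reads == other.total_reads
            and all(np.array_equal(self.counts[s], other.counts[s]) for s in STRANDS)
        )


@dataclass
class TranscriptModel:
    """A gene/transcript span with Rend-Seq end annotations.

    ``five_prime_ends`` / ``three_prime_ends`` are genomic positions of
    annotated transcript boundaries (strand-aware: on the minus strand the
    5' end has the larger coordinate).  They default to the span boundaries.
    """

    gene_id: str
    strand: str
    start: int
    end: int  # half-open
    cds_start: int | None = None
    cds_end: int | None = None  # half-open genomic CDS interval
    five_prime_ends: list[int] = field(default_factory=list)
    three_prime_ends: list[int] = field(default_factory=list)
    rpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.five_prime_ends:
            self.five_prime_ends = [self.start if self.strand == "+" else self.end - 1]
        if not self.three_prime_ends:
            self.three_prime_ends = [self.end - 1 if self.strand == "+" else self.start]
        for p in self.five_prime_ends + self.three_prime_ends:
            if not (self.start <= p < self.end):
                raise ValueError(f"{self.gene_id}: end position {p} outside span")
        if self.cds_start is not None and self.cds_end is not None:
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def to_transcript_pos(self, genomic: int) -> int:
        """0-based position along the transcript, 5' end = 0."""
        if self.strand == "+":
            return genomic - self.start
        return self.end - 1 - genomic

    def to_genomic_pos(self, tpos: int) -> int:
        if self.strand == "+":
            return self.start + tpos
        return self.end - 1 - tpos


def containing_transcript(
    models: Iterable[TranscriptModel], position: int, strand: str | None = None
) -> TranscriptModel | None:
    """The annotated span covering a position; overlaps resolve to the span
    whose midpoint is nearest the position."""
    hits = [
        m for m in models
        if m.contains(position) and (strand is None or m.strand == strand)
    ]
    if not hits:
        return None
    return min(hits, key=lambda m: (abs(m.midpoint() - position), m.gene_id))


@dataclass
class NormalizedTrack:
    """Counts over one transcript expressed as a fraction of reads mapped to it."""

    model: TranscriptModel
    values: np.ndarray  # indexed by genomic position - model.start

    def value_at(self, genomic: int) -> float:
        return float(self.values[genomic - self.model.start])


def normalize_to_transcript(track: EndCountTrack, model: TranscriptModel) -> NormalizedTrack:
    counts = track.counts[model.strand][model.start:model.end]
    total = int(counts.sum())
    if total == 0:
        raise ZeroDivisionError(
            f"{model.gene_id}: no reads mapped to transcript; normalization undefined"
        )
    return NormalizedTrack(model, counts / total)


def rpkm(track: EndCountTrack, model: TranscriptModel) -> float:
    """Reads per kilobase per million mapped reads for one gene.

    ``track.total_reads`` is the library size (mRNA-mapping reads).
    """
    if model.length <= 0:
        raise ValueError("zero-length gene")
    if track.total_reads <= 0:
        raise ValueError("library has no mapped reads")
    reads = track.window_sum(model.start, model.end, model.strand)
    return reads * 1e9 / (model.length * track.total_reads)


# ---------------------------------------------------------------------------
# Track I/O: wiggle (variableStep) and bedGraph, one strand per file.
# ---------------------------------------------------------------------------

def read_track(
    path: str | Path,
    format: str,
    strand: str = "+",
    length: int | None = None,
    library_label: str = "",
    total_reads: int | None = None,
) -> EndCountTrack:
    """Read a single-strand count track.

    Zero-count positions may be implicit.  ``length`` fixes the genome length;
    if omitted it is inferred as max position + 1.
    """
    path = Path(path)
    if format == "wiggle":
        pos, cnt = _parse_wiggle(path)
    elif format == "bedGraph":
        pos, cnt = _parse_bedgraph(path)
    else:
        raise ValueError(f"unknown track format {format!r}")
    if length is None:
        length = (max(pos) + 1) if pos else 1
    track = EndCountTrack(length, library_label=library_label)
    for p, c in zip(pos, cnt):
        if p >= length:
            raise TrackValidationError(f"position {p} beyond genome length {length}")
        track.counts[strand][p] += c
    track.total_reads = track.positional_sum()
    if total_reads is not None:
        if total_reads < track.total_reads:
            raise TrackValidationError("total_reads below positional sum")
        track.total_reads = total_reads
    return track


def _parse_wiggle(path: Path) -> tuple[list[int], list[int]]:
    positions: list[int] = []
    counts: list[int] = []
    in_block = False
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                in_block = True
                continue
            if line.startswith("fixedStep"):
                raise TrackParseError(f"{path}:{ln}: fixedStep wiggle not supported")
            fields = line.split()
            if not in_block or len(fields) != 2:
                raise TrackParseError(f"{path}:{ln}: malformed wiggle line {line!r}")
            try:
                pos1 = int(fields[0])
                val = float(fields[1])
            except ValueError as e:
                raise TrackParseError(f"{path}:{ln}: {e}") from None
            if val < 0:
                raise TrackValidationError(f"{path}:{ln}: negative count {val}")
            if pos1 < 1:
                raise TrackParseError(f"{path}:{ln}: wiggle positions are 1-based")
            positions.append(pos1 - 1)  # to 0-based
            counts.append(int(round(val)))
    return positions, counts


def _parse_bedgraph(path: Path) -> tuple[list[int], list[int]]:
    positions: list[int] = []
    counts: list[int] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise TrackParseError(f"{path}:{ln}: expected 4 bedGraph columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                val = float(fields[3])
            except ValueError as e:
                raise TrackParseError(f"{path}:{ln}: {e}") from None
            if val < 0:
                raise TrackValidationError(f"{path}:{ln}: negative count {val}")
            if start < 0 or end <= start:
                raise TrackParseError(f"{path}:{ln}: bad interval [{start}, {end})")
            for p in range(start, end):
                positions.append(p)
                counts.append(int(round(val)))
    return positions, counts


def write_track(
    track: EndCountTrack,
    path: str | Path,
    format: str,
    strand: str = "+",
    chrom: str = "genome",
) -> None:
    """Write one strand of a track; zero positions are implicit."""
    arr = track.counts[strand]
    nz = np.nonzero(arr)[0]
    with open(path, "w") as fh:
        if format == "wiggle":
            fh.write(f"variableStep chrom={chrom}\n")
            for p in nz:
                fh.write(f"{p + 1} {arr[p]}\n")  # wiggle is 1-based
        elif format == "bedGraph":
            for p in nz:
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{arr[p]}\n")
        else:
            raise ValueError(f"unknown track format {format!r}")


# ---------------------------------------------------------------------------
# Genome and annotation I/O
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> GenomeSequence:
    record = next(SeqIO.parse(str(path), "fasta"))
    return GenomeSequence(record.id, str(record.seq))


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, len(genome), width):
            fh.write(genome.sequence[i:i + width] + "\n")


def read_transcript_models(gff_path: str | Path) -> list[TranscriptModel]:
    """Build transcript models from a GFF3 subset (gene + CDS features).

    CDS features are attached to genes by ID/Parent attributes or containment.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        cds_start = cds_end = None
        for cds in db.features_of_type("CDS"):
            parent = cds.attributes.get("Parent", [None])[0]
            inside = cds.start - 1 >= gene.start - 1 and cds.end <= gene.end
            if parent == gid or (parent is None and inside and cds.strand == gene.strand):
                cds_start, cds_end = cds.start - 1, cds.end  # GFF is 1-based closed
                break
        models.append(
            TranscriptModel(
                gene_id=gid, strand=gene.strand,
                start=gene.start - 1, end=gene.end,
                cds_start=cds_start, cds_end=cds_end,
            )
        )
    return models


def write_transcript_gff(models: Iterable[TranscriptModel], path: str | Path,
                         chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{chrom}\tpsistop\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            if m.cds_start is not None and m.cds_end is not None:
                fh.write(
                    f"{chrom}\tpsistop\tCDS\t{m.cds_start + 1}\t{m.cds_end}\t.\t"
                    f"{m.strand}\t0\tParent={m.gene_id}\n"
                )


def read_ends_bed(path: str | Path, models: list[TranscriptModel]) -> None:
    """Attach Rend-Seq end annotations (BED6, name '5p' or '3p') to models in place."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    for m in models:
        m.five_prime_ends = []
        m.three_prime_ends = []
    for _, row in df.iterrows():
        pos = int(row["start"])
        m = containing_transcript(models, pos, row["strand"])
        if m is None:
            continue
        if row["name"] == "5p":
            m.five_prime_ends.append(pos)
        elif row["name"] == "3p":
            m.three_prime_ends.append(pos)
    for m in models:  # restore span-boundary defaults where nothing mapped
        if not m.five_prime_ends:
            m.five_prime_ends = [m.start if m.strand == "+" else m.end - 1]
        if not m.three_prime_ends:
            m.three_prime_ends = [m.end - 1 if m.strand == "+" else m.start]


def write_ends_bed(models: Iterable[TranscriptModel], path: str | Path,
                   chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        for m in models:
            for p in m.five_prime_ends:
                fh.write(f"{chrom}\t{p}\t{p + 1}\t5p\t0\t{m.strand}\n")
            for p in m.three_prime_ends:
                fh.write(f"{chrom}\t{p}\t{p + 1}\t3p\t0\t{m.strand}\n")


# ---------------------------------------------------------------------------
# Result rows
# ---------------------------------------------------------------------------

@dataclass
class SiteCall:
    """One candidate uridine: per-library Z-scores, coverage, call and assignment."""

    position: int  # 0-based U position on the coding strand
    strand: str
    gene_id: str
    z_by_library: dict[str, float | None] = field(default_factory=dict)
    covered_by_library: dict[str, bool] = field(default_factory=dict)
    status: str = "not_called"  # called | not_called | insufficient
    assignment: str = "none"  # enzyme name | ambiguous | unassigned | none

    def __post_init__(self) -> None:
        if self.status != "called" and self.assignment != "none":
            raise ValueError("assignment requires a called site")


def site_calls_to_frame(calls: Iterable[SiteCall]) -> pd.DataFrame:
    """Tabulate site calls with one z_/covered_ column pair per library."""
    calls = list(calls)
    labels: list[str] = []
    for c in calls:
        for lab in c.z_by_library:
            if lab not in labels:
                labels.append(lab)
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "position": c.position, "strand": c.strand, "gene_id": c.gene_id,
            "status": c.status, "assignment": c.assignment,
        }
        for lab in labels:
            z = c.z_by_library.get(lab)
            row[f"z_{lab}"] = np.nan if z is None else z
            row[f"covered_{lab}"] = c.covered_by_library.get(lab, False)
        rows.append(row)
    cols = ["position", "strand", "gene_id", "status", "assignment"]
    cols += [f"z_{lab}" for lab in labels] + [f"covered_{lab}" for lab in labels]
    return pd.DataFrame(rows, columns=cols)


def write_sites_tsv(calls: Iterable[SiteCall], path: str | Path) -> None:
    site_calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
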