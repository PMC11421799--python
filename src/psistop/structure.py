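"""Reactivity-constrained secondary-structure context around sites.

Workflow: extract the 100-nt window surrounding each site together with its
DMS reactivities (A/C only; all other positions carry the placeholder -999),
emit a constraint table, fold with a pluggable engine returning a base-pair
probability matrix (partition-function mode, 37 degC), sum the matrix
columns into a per-position pairing probability, and aggregate profiles
across a site set by position relative to the site.

The folding engine is an adapter behind a minimal contract (sequence +
optional constraints -> symmetric probability matrix).  A deterministic stub
engine supports testing; :class:`ViennaRNAEngine` drives the external RNAfold
program with soft SHAPE-style constraints when it is installed.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .tracks import GenomeSequence

#: Placeholder reactivity for non-A/C and missing positions.
NO_DATA = -999.0

#: Half-width of the window around each site (100 nt surrounding the site).
DEFAULT_FLANK = 50


class FoldingError(RuntimeError):
    """The folding engine failed; the message carries its diagnostics."""


@dataclass
class ReactivityWindow:
    """Sequence window centered on a site, with per-position DMS reactivities.

    ``reactivities[i]`` belongs to ``sequence[i]``; positions that are not A
    or C (or have no measurement) hold :data:`NO_DATA`.
    """

    site: int
    strand: str
    sequence: str  # RNA alphabet
    reactivities: np.ndarray

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        self.reactivities = np.asarray(self.reactivities, dtype=float)
        if len(self.sequence) != self.reactivities.size:
            raise ValueError("sequence and reactivities lengths differ")
        bad = [
            i for i, b in enumerate(self.sequence)
            if b not in "AC" and self.reactivities[i] != NO_DATA
        ]
        if bad:
            raise ValueError(
                f"reactivities present at non-A/C positions {bad[:5]}"
            )

    @property
    def center(self) -> int:
        return len(self.sequence) // 2


def extract_window(
    genome: GenomeSequence,
    site: int,
    strand: str,
    reactivity_by_position: Mapping[int, float] | None = None,
    flank: int = DEFAULT_FLANK,
) -> ReactivityWindow:
    """Build the reactivity window for one genomic site (strand-aware).

    ``reactivity_by_position`` maps genomic position to DMS reactivity;
    entries for non-A/C bases are ignored.
    """
    start, end = site - flank, site + flank + 1
    seq = genome.subseq(start, end, strand).replace("T", "U")
    react = np.full(len(seq), NO_DATA)
    if reactivity_by_position:
        for i in range(len(seq)):
            g = start + i if strand == "+" else end - 1 - i
            if seq[i] in "AC" and g in reactivity_by_position:
                react[i] = reactivity_by_position[g]
    return ReactivityWindow(site=site, strand=strand, sequence=seq, reactivities=react)


def prepare_constraints(window: ReactivityWindow) -> pd.DataFrame:
    """Constraint table (1-based position, reactivity); -999 marks no data."""
    return pd.DataFrame({
        "position": np.arange(1, len(window.sequence) + 1),
        "reactivity": window.reactivities,
    })


def write_constraints(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep=" ", header=False, index=False,
                 float_format="%.6g")


def read_constraints(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None,
                       names=["position", "reactivity"])


def validate_pairing_matrix(matrix: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pairing matrix must be square")
    if not np.allclose(m, m.T, atol=tol):
        raise ValueError("pairing matrix must be symmetric")
    if (m < -tol).any() or (m > 1 + tol).any():
        raise ValueError("pairing probabilities must lie in [0, 1]")
    return m


class FoldingEngine(Protocol):
    """Contract: sequence + optional constraints -> base-pair probability matrix."""

    def fold(self, sequence: str,
             constraints: pd.DataFrame | None = None) -> np.ndarray: ...


class StubEngine:
    """Deterministic test engine returning a configured matrix.

    ``matrix`` may be a fixed array (returned for every input) or a callable
    ``(sequence, constraints) -> matrix``.
    """

    def __init__(self, matrix: np.ndarray | Callable[..., np.ndarray]):
        self._matrix = matrix

    def fold(self, sequence: str,
             constraints: pd.DataFrame | None = None) -> np.ndarray:
        m = (self._matrix(sequence, constraints) if callable(self._matrix)
             else self._matrix)
        return validate_pairing_matrix(m)


class ViennaRNAEngine:
    """Adapter over the RNAfold program (partition-function mode, 37 degC).

    Constraints, when given, are passed as SHAPE-style soft constraints with
    the Z-score-based conversion of reactivities to pairing pseudo-energies.
    """

    def __init__(self, executable: str = "RNAfold", temperature: float = 37.0,
                 shape_method: str = "Z"):
        self.executable = executable
        self.temperature = temperature
        self.shape_method = shape_method

    def fold(self, sequence: str,
             constraints: pd.DataFrame | None = None) -> np.ndarray:
        seq = sequence.upper().replace("T", "U")
        with tempfile.TemporaryDirectory() as tmp:
            tmpdir = Path(tmp)
            cmd = [self.executable, "-p", "-T", str(self.temperature),
                   "--noPS"]
            if constraints is not None:
                shape_path = tmpdir / "reactivities.dat"
                write_constraints(constraints, shape_path)
                cmd += [f"--shape={shape_path}",
                        f"--shapeMethod={self.shape_method}"]
            proc = subprocess.run(
                cmd, input=f">window\n{seq}\n", text=True,
                capture_output=True, cwd=tmpdir,
            )
            if proc.returncode != 0:
                raise FoldingError(
                    f"{self.executable} failed ({proc.returncode}): {proc.stderr}"
                )
            dp = tmpdir / "window_dp.ps"
            if not dp.exists():
                raise FoldingError("RNAfold produced no dot-plot output")
            return _parse_dot_plot(dp, len(seq))


def _parse_dot_plot(path: Path, n: int) -> np.ndarray:
    """Parse pair probabilities from an RNAfold dot-plot file.

    Ensemble entries are lines ``i j sqrt(p) ubox`` with 1-based indices.
    """
    matrix = np.zeros((n, n))
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 4 and parts[3] == "ubox":
                try:
                    i, j = int(parts[0]), int(parts[1])
                    sq = float(parts[2])
                except ValueError:
                    continue  # header line such as '%  i  j  sqrt(p) ubox'
                p = sq * sq
                matrix[i - 1, j - 1] = p
                matrix[j - 1, i - 1] = p
    return validate_pairing_matrix(matrix)


def fold(
    window: ReactivityWindow,
    constraints: pd.DataFrame | None = None,
    engine: FoldingEngine | None = None,
) -> np.ndarray:
    """Fold a window into a validated base-pair probability matrix.

    With no engine given, the external RNAfold adapter is used.  Passing
    ``constraints=None`` folds unconstrained.
    """
    eng = engine if engine is not None else ViennaRNAEngine()
    matrix = eng.fold(window.sequence, constraints)
    return validate_pairing_matrix(matrix)


def pairing_profile(matrix: np.ndarray, warn_excess: float = 0.05) -> np.ndarray:
    """Per-position pairing probability: column sums of the matrix, clipped to [0,1].

    A column sum exceeding 1 by more than ``warn_excess`` indicates an
    inconsistent matrix and triggers a warning.
    """
    m = validate_pairing_matrix(matrix)
    sums = m.sum(axis=1)
    excess = float(np.max(sums - 1.0, initial=0.0))
    if excess > warn_excess:
        warnings.warn(
            f"pairing-probability column sums exceed 1 by {excess:.3f}; "
            "matrix may be inconsistent", RuntimeWarning,
        )
    return np.clip(sums, 0.0, 1.0)


@dataclass
class PairingSummary:
    """Per-relative-offset distribution of pairing probabilities over sites."""

    offsets: np.ndarray  # -flank .. +flank
    values: np.ndarray  # sites x offsets, raw per-site profiles
    site_ids: list = field(default_factory=list)

    def median(self) -> np.ndarray:
        return np.median(self.values, axis=0)

    def quartiles(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.percentile(self.values, 25, axis=0),
                np.percentile(self.values, 75, axis=0))

    def to_frame(self) -> pd.DataFrame:
        q25, q75 = self.quartiles()
        return pd.DataFrame({
            "offset": self.offsets,
            "median": self.median(),
            "q25": q25,
            "q75": q75,
        })


def aggregate_relative(
    site_profiles: Sequence[np.ndarray],
    sites: Sequence | None = None,
) -> PairingSummary:
    """Aggregate per-site pairing profiles by position relative to the site.

    Every profile must be centered on its site and share one length; raw
    values are retained, with medians and quartiles derived on demand.
    Deterministic and invariant to site ordering.
    """
    if not site_profiles:
        raise ValueError("no profiles to aggregate")
    lengths = {len(p) for p in site_profiles}
    if len(lengths) != 1:
        raise ValueError("profiles must share one window length")
    n = lengths.pop()
    flank = n // 2
    values = np.vstack([np.asarray(p, dtype=float) for p in site_profiles])
    return PairingSummary(
        offsets=np.arange(-flank, n - flank),
        values=values,
        site_ids=list(sites) if sites is not None else list(range(len(site_profiles))),
    )


def structure_context(
    genome: GenomeSequence,
    sites: Iterable[tuple[int, str]],
    reactivity_by_position: Mapping[int, float] | None = None,
    engine: FoldingEngine | None = None,
    flank: int = DEFAULT_FLANK,
) -> PairingSummary:
    """End-to-end: windows -> constraints -> fold -> profiles -> summary."""
    profiles = []
    ids = []
    for pos, strand in sites:
        w = extract_window(genome, pos, strand, reactivity_by_position, flank)
        cons = prepare_constraints(w)
        matrix = fold(w, cons, engine)
        profiles.append(pairing_profile(matrix))
        ids.append((pos, strand))
    return aggregate_relative(profiles, ids)
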