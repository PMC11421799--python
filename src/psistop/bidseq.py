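"""Deletion-rate quantification for targeted bisulfite sequencing (BID-seq).

Bisulfite chemistry converts a pseudouridine into a 1-2 nt deletion whose
frequency is roughly proportional to the modification stoichiometry.  This
module turns per-position (deletions, depth) pileups into deletion-rate
traces and summarizes the signal at a site as the maximum rate within a
small window (default +/-2 nt), absorbing the 1-2 nt register spread of the
deletion signature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def deletion_trace(pileup: pd.DataFrame) -> pd.DataFrame:
    """Per-position deletion rates from a (position, depth, deletions) table.

    Zero-depth positions get an undefined (NaN) rate, not zero.  Raises on
    negative counts or deletions exceeding depth.
    """
    required = {"position", "depth", "deletions"}
    missing = required - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    df = pileup[["position", "depth", "deletions"]].copy()
    if (df["depth"] < 0).any() or (df["deletions"] < 0).any():
        raise ValueError("negative counts in pileup")
    if (df["deletions"] > df["depth"]).any():
        raise ValueError("deletions exceed depth")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = df["deletions"] / df["depth"]
    df["rate"] = rate.where(df["depth"] > 0, np.nan)
    return df


def site_signal(trace: pd.DataFrame, site: int, halfwidth: int = 2) -> float:
    """Deletion signal at a site: max rate within ``halfwidth`` nt of it.

    NaN (zero-depth) positions are ignored; a site whose whole window is
    undefined or empty yields NaN.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be non-negative")
    sel = trace[(trace["position"] >= site - halfwidth)
                & (trace["position"] <= site + halfwidth)]
    if sel.empty or sel["rate"].isna().all():
        return float("nan")
    return float(sel["rate"].max())


def compare_conditions(
    traces: dict[str, pd.DataFrame], sites: list[int], halfwidth: int = 2
) -> pd.DataFrame:
    """Per-site signal across conditions (e.g. WT vs a knockout strain)."""
    rows = []
    for site in sites:
        row: dict[str, object] = {"site": site}
        for label, trace in traces.items():
            row[label] = site_signal(trace, site, halfwidth)
        rows.append(row)
    return pd.DataFrame(rows)
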