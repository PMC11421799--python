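"""Pipeline configuration and the end-to-end driver.

A single YAML (or dict) config declares either a synthetic-data block or a
set of labelled library files, plus thresholds and per-stage options; the
driver wires simulate -> call -> assign -> saturate -> motif -> structure ->
bidseq and writes TSV outputs with a JSON run manifest recording versions,
seeds and thresholds.  Library roles (condition, knockout enzyme) are
declared explicitly in the config, never inferred from filenames.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assign import assign_sites
from .bidseq import compare_conditions, deletion_trace
from .motifs import classify_motif, position_frequency, select_background
from .peaks import CallThresholds, scan_transcriptome
from .saturation import pool_tracks, saturation_curve
from .simulate import (
    PlantedSite,
    SimulationConfig,
    make_transcriptome,
    simulate_bidseq_pileup,
    simulate_pseudoseq_suite,
)
from .tracks import (
    EndCountTrack,
    read_ends_bed,
    read_genome,
    read_track,
    read_transcript_models,
    rpkm,
    site_calls_to_frame,
    write_sites_tsv,
)


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    raw: dict[str, Any]
    outdir: Path
    seed: int
    thresholds: CallThresholds
    window_len: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path = Path(".")) -> "PipelineConfig":
        raw = dict(raw)
        outdir = Path(raw.get("outdir", "psistop_out"))
        if not outdir.is_absolute():
            outdir = base / outdir
        thresholds = CallThresholds(**raw.get("thresholds", {}))
        cfg = cls(
            raw=raw, outdir=outdir, seed=int(raw.get("seed", 0)),
            thresholds=thresholds, window_len=int(raw.get("window_len", 100)),
        )
        cfg._validate(base)
        return cfg

    def _validate(self, base: Path) -> None:
        libs = self.raw.get("libraries")
        sim = self.raw.get("simulate")
        if libs is None and sim is None:
            raise ConfigurationError("config needs a 'libraries' or 'simulate' block")
        if libs is not None:
            labels = [entry.get("label") for entry in libs]
            if len(set(labels)) != len(labels):
                raise ConfigurationError("library labels must be unique")
            roles = [entry.get("role") for entry in libs]
            if "cmc" not in roles or "mock" not in roles:
                raise ConfigurationError(
                    "libraries must include roles 'cmc' (WT-CMC) and 'mock' (WT-mock)"
                )
            for entry in libs:
                for key in ("plus", "minus"):
                    if key in entry and not (base / entry[key]).exists():
                        raise ConfigurationError(f"missing track file {entry[key]}")


def _load_libraries(cfg: PipelineConfig, base: Path):
    genome = read_genome(base / cfg.raw["genome"])
    models = read_transcript_models(base / cfg.raw["genes"])
    if "ends" in cfg.raw:
        read_ends_bed(base / cfg.raw["ends"], models)
    tracks: dict[str, EndCountTrack] = {}
    roles: dict[str, str] = {}
    for entry in cfg.raw["libraries"]:
        label = entry["label"]
        fmt = entry.get("format", "wiggle")
        track = EndCountTrack(len(genome), library_label=label)
        for strand, key in (("+", "plus"), ("-", "minus")):
            if key in entry:
                part = read_track(base / entry[key], fmt, strand=strand,
                                  length=len(genome))
                track.counts[strand] += part.counts[strand]
        track.total_reads = int(entry.get("total_reads", track.positional_sum()))
        role = entry.get("role", "knockout")
        if role == "cmc":
            roles["WT-CMC"] = label
        elif role == "mock":
            roles["WT-mock"] = label
        tracks[label] = track
    return genome, models, tracks, roles


def _simulate_inputs(cfg: PipelineConfig):
    sim = dict(cfg.raw["simulate"])
    sites = [
        PlantedSite(
            gene_id=s["gene"], u_position=int(s["u"]),
            enzyme=s.get("enzyme", "rluA"),
            stop_efficiency=float(s.get("efficiency", 0.9)),
            stoichiometry=float(s.get("stoichiometry", 1.0)),
        )
        for s in sim.pop("sites", [])
    ]
    knockouts = sim.pop("knockouts", [])
    sc = SimulationConfig(planted_sites=sites, seed=cfg.seed, **sim)
    transcriptome = make_transcriptome(sc)
    tracks = simulate_pseudoseq_suite(sc, transcriptome, knockouts=knockouts)
    roles = {"WT-CMC": "WT-CMC", "WT-mock": "WT-mock"}
    return transcriptome, sc, tracks, roles, knockouts


def run_end_to_end(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the configured pipeline stages; returns paths of written outputs."""
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    base = Path(cfg.raw.get("_base", "."))

    if "simulate" in cfg.raw:
        transcriptome, sc, tracks, roles, knockouts = _simulate_inputs(cfg)
        genome, models = transcriptome.genome, transcriptome.models
        truth_path = outdir / "truth.tsv"
        transcriptome.truth_table().to_csv(truth_path, sep="\t", index=False)
        outputs["truth"] = truth_path
    else:
        genome, models, tracks, roles = _load_libraries(cfg, base)
        knockouts = [
            entry["enzyme"] for entry in cfg.raw["libraries"]
            if entry.get("role") == "knockout"
        ]

    # attach expression levels for background selection
    for m in models:
        m.rpkm = rpkm(tracks[roles["WT-CMC"]], m)

    ko_labels = {e: f"d{e}-CMC" for e in knockouts if f"d{e}-CMC" in tracks}
    calls = scan_transcriptome(
        tracks, genome, models, thresholds=cfg.thresholds,
        window_len=cfg.window_len, cmc_label=roles["WT-CMC"],
        mock_label=roles["WT-mock"], extra_labels=list(ko_labels.values()),
    )
    sites_path = outdir / "sites.tsv"
    write_sites_tsv(calls, sites_path)
    outputs["sites"] = sites_path

    if ko_labels:
        assign_sites(calls, cmc_label=roles["WT-CMC"], ko_labels=ko_labels,
                     thresholds=cfg.thresholds)
        assigned_path = outdir / "assigned.tsv"
        write_sites_tsv(calls, assigned_path)
        outputs["assigned"] = assigned_path

    called = [(c.position, c.strand) for c in calls if c.status == "called"]

    sat = cfg.raw.get("saturation")
    if sat:
        pool = pool_tracks([tracks[roles["WT-CMC"]]])
        mock_pool = pool_tracks([tracks[roles["WT-mock"]]])
        curve = saturation_curve(
            pool, [int(d) for d in sat["depths"]], mock_pool, genome, models,
            thresholds=cfg.thresholds, seed=cfg.seed, window_len=cfg.window_len,
        )
        curve_path = outdir / "curve.tsv"
        curve.to_frame().to_csv(curve_path, sep="\t", index=False)
        outputs["curve"] = curve_path

    if called:
        flank = int(cfg.raw.get("motif", {}).get("flank", 5))
        pfm = position_frequency(called, genome, flank=flank)
        pfm_path = outdir / "motif_pfm.tsv"
        pfm.to_csv(pfm_path, sep="\t")
        outputs["motif_pfm"] = pfm_path
        classes = pd.DataFrame({
            "position": [p for p, _ in called],
            "strand": [s for _, s in called],
            "motif_class": [classify_motif(genome, p, s) for p, s in called],
        })
        cls_path = outdir / "motif_classes.tsv"
        classes.to_csv(cls_path, sep="\t", index=False)
        outputs["motif_classes"] = cls_path

        bg_cfg = cfg.raw.get("background", {})
        background = select_background(
            models, genome, called,
            rpkm_min=float(bg_cfg.get("rpkm_min", 105.0)),
            exclusion_nt=int(bg_cfg.get("exclusion_nt", 100)),
            n_max=bg_cfg.get("n_max"), seed=cfg.seed,
        )
        bg_path = outdir / "background_sites.tsv"
        pd.DataFrame(background, columns=["position", "strand"]).to_csv(
            bg_path, sep="\t", index=False)
        outputs["background"] = bg_path

    bid = cfg.raw.get("bidseq")
    if bid and "simulate" in cfg.raw:
        truth = transcriptome.truth_table()
        local = {int(r.transcript_u_position): float(r.stoichiometry)
                 for r in truth.itertuples()}
        depth = int(bid.get("depth", 10_000))
        wt = simulate_bidseq_pileup(
            sorted(local), local, depth, seed=cfg.seed,
            length=sc.transcript_length)
        ko = simulate_bidseq_pileup(
            sorted(local), {k: 0.0 for k in local}, depth, seed=cfg.seed + 1,
            length=sc.transcript_length)
        table = compare_conditions(
            {"WT": deletion_trace(wt), "KO": deletion_trace(ko)}, sorted(local))
        bid_path = outdir / "bidseq_signal.tsv"
        table.to_csv(bid_path, sep="\t", index=False)
        outputs["bidseq"] = bid_path

    manifest = {
        "psistop_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "window_len": cfg.window_len,
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "outputs": {k: str(v) for k, v in outputs.items()},
        "n_called": len(called),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = manifest_path
    return outputs
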