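"""Config-driven end-to-end study analog.

One config drives the whole chain: simulate an ancestral bait source and
a diverged target genome, tile baits, simulate capture and shotgun
libraries plus a panel of capture samples in two matrilines, then filter
by MAPQ, remove duplicates, call consensus, run the window
divergence-response analysis, recover the capture model, and build the
haplotype network.  All stage seeds derive from the single config seed,
so rerunning a config reproduces every artifact byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from anccap import baitdesign, consensus, dedup, haplonet, seqio, simgen, windows

log = logging.getLogger(__name__)


@dataclass
class SimulateConfig:
    genome_length: int = 16500
    gc: float = 0.40
    track: list[tuple[int, int, float]] | None = None  # None -> default profile
    capture_fragments: int = 20000
    shotgun_fragments: int = 20000
    sample_fragments: int = 6000
    length_mean: float = 70.0
    length_sd: float = 25.0
    min_length: int = 30
    damage_rate: float = 0.3
    damage_decay: float = 0.5
    damage_enabled: bool = True
    p_max: float = 0.95
    id_50: float = 0.80
    slope: float = 40.0
    dup_rate: float = 0.15
    n_samples: int = 8
    matriline_divergence: float = 0.01
    within_matriline_divergence: float = 0.001
    capture_enabled: bool = True


@dataclass
class AnalysisConfig:
    min_depth: int = 3
    majority: float = 0.90
    mapq: int = 30
    bait_length: int = 60
    bait_step: int = 2
    window: int = 60
    window_step: int = 30
    region: tuple[int, int] = (2000, 15000)
    bin_width: float = 0.02
    n_boot: int = 200


@dataclass
class RunConfig:
    seed: int = 42
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim_raw = dict(raw.get("simulate", {}))
        ana_raw = dict(raw.get("analysis", {}))
        for block, klass in ((sim_raw, SimulateConfig), (ana_raw, AnalysisConfig)):
            unknown = set(block) - {f.name for f in dataclasses.fields(klass)}
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = SimulateConfig(**sim_raw)
        if sim.track is not None:
            sim.track = [tuple(seg) for seg in sim.track]
        ana = AnalysisConfig(**ana_raw)
        if "region" in ana_raw:
            ana.region = tuple(ana_raw["region"])
        return cls(seed=int(raw.get("seed", 42)), simulate=sim, analysis=ana)


@dataclass
class SampleRow:
    """Per-sample recovery summary (the standard capture-paper table row)."""

    sample_id: str
    mode: str
    unique_mapped_reads: int
    duplicates_removed: int
    portion_at_min_depth: float
    mean_depth: float


@dataclass
class RunReport:
    samples: list[SampleRow]
    response: "windows.pd.DataFrame"
    fit: windows.CaptureModelFit | None
    partition: tuple[list[str], list[str]] | None
    split_length: int | None
    whole_molecule_identity: float
    mean_window_divergence: float
    n_windows: int

    def to_dict(self) -> dict:
        return {
            "samples": [dataclasses.asdict(s) for s in self.samples],
            "response": self.response.to_dict(orient="records"),
            "fit": dataclasses.asdict(self.fit) if self.fit else None,
            "partition": [sorted(self.partition[0]), sorted(self.partition[1])] if self.partition else None,
            "split_length": self.split_length,
            "whole_molecule_identity": self.whole_molecule_identity,
            "mean_window_divergence": self.mean_window_divergence,
            "n_windows": self.n_windows,
        }


def _uniform_track(length: int, divergence: float) -> simgen.DivergenceTrack:
    return simgen.DivergenceTrack([(0, length, divergence)])


def _process_library(lib, mapq):
    filtered = seqio.filter_mapq(lib.reads, mapq)
    unique, n_dup = dedup.mark_duplicates_start_end(filtered) if filtered else ([], 0)
    return unique, n_dup


def run(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute every stage in fixed order and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim, ana = config.simulate, config.analysis
    seed = config.seed
    t0 = time.time()
    manifest: list[str] = []

    def _write(name, writer, *args):
        path = outdir / name
        writer(*args, path)
        manifest.append(name)
        return path

    # --- simulate ---------------------------------------------------------
    L = sim.genome_length
    ancestor = simgen.generate_ancestral(L, sim.gc, seed)
    track = (
        simgen.DivergenceTrack(list(sim.track)) if sim.track is not None
        else simgen.default_divergence_track(L)
    )
    descendant, truth = simgen.evolve_descendant(ancestor, track, seed + 1)
    _write("ancestor.fasta", seqio.write_fasta, [ancestor])
    _write("target.fasta", seqio.write_fasta, [descendant])
    _write("truth_substitutions.tsv", simgen.write_truth_table, truth)
    log.info("simulate: genome %d bp, %d substitutions", L, len(truth))

    baits = baitdesign.design_baits(ancestor, ana.bait_length, ana.bait_step)
    _write("baits.fasta", baitdesign.write_baits_fasta, baits)
    log.info("baits: %d tiles of %d bp at step %d", len(baits), ana.bait_length, ana.bait_step)

    frag = simgen.FragmentModel(
        n_fragments=0, length_mean=sim.length_mean, length_sd=sim.length_sd, min_length=sim.min_length
    )
    damage = simgen.DamageModel(rate_5prime=sim.damage_rate, decay=sim.damage_decay, enabled=sim.damage_enabled)
    capture_model = simgen.CaptureModel(p_max=sim.p_max, id_50=sim.id_50, slope=sim.slope)

    def _simulate(genome, n, mode, lib_seed, sample_id):
        f = dataclasses.replace(frag, n_fragments=n)
        return simgen.simulate_library(
            genome, f, damage, mode,
            baits=baits if mode == "capture" else None,
            capture=capture_model if mode == "capture" else None,
            dup_rate=sim.dup_rate, seed=lib_seed, sample_id=sample_id,
        )

    focal_mode = "capture" if sim.capture_enabled else "shotgun"
    cap_lib = _simulate(descendant, sim.capture_fragments, focal_mode, seed + 2, "focal_capture")
    sho_lib = _simulate(descendant, sim.shotgun_fragments, "shotgun", seed + 3, "focal_shotgun")
    _write("focal_capture.sam", seqio.write_sam, cap_lib.reads, descendant)
    _write("focal_shotgun.sam", seqio.write_sam, sho_lib.reads, descendant)

    # --- filter / dedup / consensus on the focal libraries ----------------
    params = consensus.ConsensusParams(min_depth=ana.min_depth, majority=ana.majority)
    samples: list[SampleRow] = []
    focal_unique = {}
    for lib in (cap_lib, sho_lib):
        unique, n_dup = _process_library(lib, ana.mapq)
        focal_unique[lib.sample_id] = unique
        pile = consensus.pileup(unique, L)
        cons = consensus.call_consensus(pile, params, ref_id=f"{lib.sample_id}_consensus")
        frac, mean_depth = consensus.completeness(cons, params)
        samples.append(SampleRow(lib.sample_id, lib.mode, len(unique), n_dup, frac, mean_depth))
        _write(f"{lib.sample_id}.consensus.fasta", consensus.write_consensus_fasta, cons)
        _write(f"{lib.sample_id}.depth.bedgraph", consensus.write_depth_bedgraph, cons)

    # --- windows ----------------------------------------------------------
    wparams = windows.WindowParams(
        window=ana.window, step=ana.window_step, region=tuple(ana.region), bin_width=ana.bin_width
    )
    wins = windows.window_identity(ancestor.bases, descendant.bases, wparams)
    windows.window_depth(focal_unique["focal_capture"], wins, L, which="capture")
    windows.window_depth(focal_unique["focal_shotgun"], wins, L, which="shotgun")
    _write("windows.bed", windows.write_window_bed, wins, ancestor.id)
    response = windows.divergence_response(wins, wparams)
    response.to_csv(outdir / "divergence_response.tsv", sep="\t", index=False, float_format="%.6g")
    manifest.append("divergence_response.tsv")
    windows.plot_response(response, outdir / "divergence_response.png")
    manifest.append("divergence_response.png")

    fit: windows.CaptureModelFit | None
    try:
        fit = windows.fit_capture_model(wins, n_boot=ana.n_boot, seed=seed + 4)
    except ValueError as exc:
        log.warning("capture-model fit skipped: %s", exc)
        fit = None
    else:
        with open(outdir / "capture_model_fit.json", "w") as fh:
            json.dump(dataclasses.asdict(fit), fh, indent=2, sort_keys=True)
        manifest.append("capture_model_fit.json")

    aln = windows.align_banded(ancestor.bases, descendant.bases)
    clean = [w for w in wins if not w.has_gap]
    mean_div = float(np.mean([w.divergence for w in clean])) if clean else float("nan")

    # --- sample panel in two matrilines -----------------------------------
    partition = None
    split_length = None
    if sim.n_samples >= 2:
        founder_b, _ = simgen.evolve_descendant(
            descendant, _uniform_track(L, sim.matriline_divergence), seed + 5
        )
        founders = {"A": descendant, "B": founder_b}
        sample_ids, rows = [], []
        half = sim.n_samples // 2
        for i in range(sim.n_samples):
            group = "A" if i < half else "B"
            sid = f"SIM-{i + 1:02d}{group}"
            genome, _ = simgen.evolve_descendant(
                founders[group], _uniform_track(L, sim.within_matriline_divergence), seed + 10 + i
            )
            lib = _simulate(genome, sim.sample_fragments, focal_mode, seed + 40 + i, sid)
            unique, n_dup = _process_library(lib, ana.mapq)
            pile = consensus.pileup(unique, L)
            cons = consensus.call_consensus(pile, params, ref_id=f"{sid}_consensus")
            frac, mean_depth = consensus.completeness(cons, params)
            samples.append(SampleRow(sid, lib.mode, len(unique), n_dup, frac, mean_depth))
            _write(f"{sid}.consensus.fasta", consensus.write_consensus_fasta, cons)
            sample_ids.append(sid)
            rows.append(cons.calls.replace("-", "N"))
        stripped = consensus.strip_missing_columns(rows)
        net = haplonet.build_network(sample_ids, stripped)
        haplonet.write_network(net, outdir / "network_edges.tsv", outdir / "network_partition.tsv")
        manifest += ["network_edges.tsv", "network_partition.tsv"]
        if net.partition is not None:
            groups = []
            for side in net.partition:
                members: list[str] = []
                for hap in side:
                    members += net.nodes[hap][1]
                groups.append(sorted(members))
            groups.sort()
            partition = (groups[0], groups[1])
            split_length = net.split_length

    report = RunReport(
        samples=samples, response=response, fit=fit,
        partition=partition, split_length=split_length,
        whole_molecule_identity=aln.identity,
        mean_window_divergence=mean_div, n_windows=len(wins),
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    manifest.append("report.json")
    with open(outdir / "manifest.tsv", "w") as fh:
        for name in sorted(manifest):
            fh.write(name + "\n")
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return report
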