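"""Pipeline orchestration: configuration, seeds, artifacts and manifests.

The canonical stage order is simulate -> callpeaks -> divergence -> evolve;
each stage writes plain-text artifacts (BED6, GFF3, TSV, wiggle) into the
output directory and the run ends with a checksum manifest, so reruns with
the same configuration and seeds are verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence, evolution, peaks, synthetic
from .io import write_bed, write_gff3, write_manifest, write_tsv, write_wiggle

#: enrichment thresholds the classification stage accepts ("auto" derives the
#: empirical permutation threshold from the reference data)
ALLOWED_THRESHOLDS = (0.35, 0.4, 0.5, 1.0)

STAGES = ("simulate", "callpeaks", "divergence", "evolve")


@dataclass
class PipelineConfig:
    stages: tuple = STAGES
    threshold: float | str = "auto"   # classification enrichment threshold
    logp_cut: float = 20.0
    peak_fdr: float = 0.01
    identity_cutoff: float = 0.5
    motif_p: float = 0.005
    expression_adj_p: float = 0.01
    expression_log2fc: float = 2.0
    seed: int = 0
    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig)

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.threshold != "auto" and float(self.threshold) not in ALLOWED_THRESHOLDS:
            raise ValueError(
                f"threshold must be 'auto' or one of {ALLOWED_THRESHOLDS}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def load_config(path, seed: int | None = None) -> PipelineConfig:
    """Flat ``key = value`` text configuration."""
    values: dict = {}
    sim: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (x.strip() for x in line.split("=", 1))
        target = sim if key.startswith("sim.") else values
        key = key.removeprefix("sim.")
        if key == "stages":
            target[key] = tuple(v.strip() for v in val.split(","))
        elif val.replace(".", "", 1).replace("-", "", 1).isdigit():
            target[key] = float(val) if "." in val else int(val)
        else:
            target[key] = val
    if seed is not None:
        values["seed"] = seed
        sim.setdefault("seed", seed)
    if sim:
        values["simulation"] = synthetic.SimulationConfig(**sim)
    return PipelineConfig(**values)


def _read_frames(reads: dict, species: str, role: str, n_reps: int):
    return [reads[(species, role, r + 1)] for r in range(n_reps)]


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run the configured stages in dependency order; returns the outdir.

    Artifacts: simulated reads (BED6), annotation (GFF3), truth tables
    (TSV), per-species peaks (TSV), per-pair classification (TSV), smoothed
    reference enrichment (wiggle), occupancy/age table, per-branch turnover
    and the divergence-time regression (TSV), plus a manifest with
    checksums of everything.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if sim.seed != config.seed:
        sim = sim.with_seed(config.seed)
    missing = [s for s in STAGES[:STAGES.index("evolve")]
               if s not in config.stages and any(
                   later in config.stages
                   for later in STAGES[STAGES.index(s) + 1:])]
    if missing:
        raise ValueError(f"stage(s) {missing} required by later stages")

    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=1,
                                                   sort_keys=True, default=str))
    log: dict = {"seed": config.seed, "stages": list(config.stages)}

    # --- simulate ---------------------------------------------------------
    annotation = synthetic.simulate_annotation(sim)
    truth = synthetic.simulate_binding_history(sim)
    reads = synthetic.simulate_chip_reads(truth, sim)
    maps, site_identity = synthetic.simulate_orthology(sim, truth)
    if "simulate" in config.stages:
        write_gff3(annotation, outdir / "annotation.gff3")
        for key, df in reads.items():
            write_bed(df, outdir / ("reads_%s_%s_%d.bed" % key))
        truth_df = pd.DataFrame(truth.presence, columns=evolution.SPECIES)
        truth_df.insert(0, "summit", truth.summits)
        truth_df["origin_branch"] = truth.origin_branch
        truth_df["age_class"] = truth.age_class
        write_tsv(truth_df, outdir / "truth_sites.tsv")
        write_tsv(site_identity, outdir / "truth_site_identity.tsv")

    # --- callpeaks --------------------------------------------------------
    peak_tables = {}
    if "callpeaks" in config.stages:
        for sp in evolution.SPECIES:
            chip = [df["start"].to_numpy() for df in
                    _read_frames(reads, sp, "chip", sim.n_replicates)]
            inp = [df["start"].to_numpy() for df in
                   _read_frames(reads, sp, "input", sim.n_replicates)]
            called, thr = peaks.call_peaks(chip, inp, sim.genome_length,
                                           annotation=annotation,
                                           seed=config.seed,
                                           chrom=sim.chrom)
            peak_tables[sp] = peaks.peaks_to_frame(called)
            log[f"peak_threshold_{sp}"] = thr
            write_tsv(peak_tables[sp], outdir / f"peaks_{sp}.tsv")

    # --- divergence -------------------------------------------------------
    pair_results = {}
    if "divergence" in config.stages:
        threshold = None if config.threshold == "auto" else float(config.threshold)
        for sp in ("sim", "yak", "pse"):
            res = divergence.analyze_pair(
                _read_frames(reads, "mel", "chip", sim.n_replicates),
                _read_frames(reads, "mel", "input", sim.n_replicates),
                _read_frames(reads, sp, "chip", sim.n_replicates),
                _read_frames(reads, sp, "input", sim.n_replicates),
                sim.genome_length, orthology_map=maps[sp],
                read_length=sim.read_length, threshold=threshold,
                logp_cut=config.logp_cut, seed=config.seed)
            pair_results[sp] = res
            write_tsv(res["classified"], outdir / f"classified_mel_{sp}.tsv")
            log[f"dropped_reads_{sp}"] = res["dropped_reads"]
            log[f"classification_threshold_{sp}"] = res["threshold"]

    # --- evolve -----------------------------------------------------------
    if "evolve" in config.stages:
        summits = truth.summits
        occupancy = np.ones((len(summits), 4), dtype=int)
        if "mel" in peak_tables and not peak_tables["mel"].empty:
            mel_peaks = peak_tables["mel"]
            covered = [bool(((mel_peaks["start"] <= s)
                             & (s < mel_peaks["end"])).any()) for s in summits]
            occupancy[:, 0] = np.asarray(covered, dtype=int)
        divergences = {}
        for j, sp in enumerate(("sim", "yak", "pse"), start=1):
            labels = divergence.assign_site_classes(
                pair_results[sp]["classified"], summits)
            shared = np.array([lab == "shared" for lab in labels])
            occupancy[:, j] = shared.astype(int)
            mel_bound = truth.presence[:, 0] == 1
            divergences[sp] = 100.0 * float((~shared[mel_bound]).mean())
        mel_sites = occupancy[:, 0] == 1
        results = [evolution.parsimony_age(vec) for vec in occupancy[mel_sites]]
        events = pd.DataFrame({
            "summit": summits[mel_sites],
            "occupancy": ["".join(map(str, v)) for v in occupancy[mel_sites]],
            "age_class": [r.age_class for r in results],
            "origin_branch": [r.origin_branch for r in results],
            "ambiguous": [r.ambiguous for r in results],
        })
        write_tsv(events, outdir / "binding_events.tsv")
        turnover = evolution.branch_turnover(results)
        write_tsv(pd.DataFrame({
            "branch": list(turnover["gains"]),
            "gains": list(turnover["gains"].values()),
            "losses": list(turnover["losses"].values()),
        }), outdir / "branch_turnover.tsv")
        times = [evolution.SPLIT_TIMES[sp] for sp in ("sim", "yak", "pse")]
        reg = evolution.divergence_rate_regression(
            [divergences[sp] for sp in ("sim", "yak", "pse")], times)
        write_tsv(pd.DataFrame([{**reg, "pairs": "sim,yak,pse"}]),
                  outdir / "divergence_regression.tsv")
        log["pairwise_divergence_percent"] = divergences
        # reference enrichment track of the closest pair, for browsing
        first = pair_results["sim"]["classified"]
        if not first.empty:
            track = np.zeros(sim.genome_length)
            for _, row in first.iterrows():
                track[int(row["start"]):int(row["end"])] = row["enrichment_ref"]
            write_wiggle(track, sim.chrom, outdir / "enrichment_mel.wig")

    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    write_manifest(outdir, config.to_dict())
    return outdir
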