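"""Self-validation experiments for the classification pipeline.

Two experiments quantify the pipeline's error bounds on synthetic data
with known truth:

* :func:`classification_validation` — a designed two-species landscape
  (half shared, half lineage-specific sites) is simulated, pushed through
  translation, normalization, the per-coordinate categorical model,
  smoothing and classification, and the calls are scored against truth
  (FPR + FNR).
* :func:`pseudo_pair_null` — one species' replicate reads are pooled and
  randomly re-split into two pseudo-species of equal depth; every site is
  shared by construction, so any site classified as specific to either
  pseudo-species is a model false positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import divergence, synthetic


def _half_shared_presence(n_sites: int) -> np.ndarray:
    """Half shared, a quarter reference-only, a quarter other-only."""
    presence = np.zeros((n_sites, 4), dtype=int)
    n_half = n_sites // 2
    n_quarter = (n_sites - n_half) // 2
    presence[:n_half] = (1, 1, 1, 1)
    presence[n_half:n_half + n_quarter] = (1, 0, 0, 0)
    presence[n_half + n_quarter:] = (0, 1, 1, 1)
    return presence


def _frames(reads, species, role, n_reps):
    return [reads[(species, role, r + 1)] for r in range(n_reps)]


def classification_validation(seed: int = 0, genome_length: int = 200_000,
                              n_sites: int = 200, enrichment: float = 8.0,
                              depth: int = 200_000,
                              pair_species: str = "sim") -> dict:
    """End-to-end misclassification of the pipeline against designed truth.

    Returns FPR, FNR and their sum (fractions), plus the per-site calls.
    """
    config = synthetic.SimulationConfig(
        genome_length=genome_length, n_sites=n_sites, depth=depth,
        enrichment=enrichment, seed=seed)
    presence = _half_shared_presence(n_sites)
    truth = synthetic.simulate_binding_history(config, presence=presence)
    reads = synthetic.simulate_chip_reads(truth, config,
                                          species=("mel", pair_species))
    maps, _ = synthetic.simulate_orthology(config, truth)
    result = divergence.analyze_pair(
        _frames(reads, "mel", "chip", config.n_replicates),
        _frames(reads, "mel", "input", config.n_replicates),
        _frames(reads, pair_species, "chip", config.n_replicates),
        _frames(reads, pair_species, "input", config.n_replicates),
        config.genome_length, orthology_map=maps[pair_species],
        read_length=config.read_length, seed=seed)
    labels = np.asarray(divergence.assign_site_classes(result["classified"],
                                                       truth.summits))
    sp_idx = synthetic.SPECIES.index(pair_species)
    truth_classes = np.where(presence[:, 0] & presence[:, sp_idx],
                             "shared", "diverged")
    # Error rates are scored over sites with orthologous sequence in the
    # pair (the two-way-orthologous notion): a site inside an unmappable
    # window loses its non-reference reads to translation, so its
    # evolutionary status is unknowable rather than misclassified.
    mask = maps[pair_species].mappable_mask()
    orthologous = np.array([mask[s - 100:s + 101].all()
                            for s in truth.summits])
    errors = divergence.estimate_error_rates(truth_classes[orthologous],
                                             labels[orthologous])
    errors["all_sites"] = divergence.estimate_error_rates(truth_classes,
                                                          labels)
    errors["n_orthologous"] = int(orthologous.sum())
    errors["labels"] = labels
    errors["threshold"] = result["threshold"]
    return errors


def pseudo_pair_null(seed: int = 0, genome_length: int = 200_000,
                     n_sites: int = 200, enrichment: float = 8.0,
                     depth: int = 200_000) -> dict:
    """Model false-positive rate on a pooled-and-resplit null dataset.

    All truth sites are shared; the second "species" is built by pooling
    the first species' reads and re-splitting them into replicates of
    equal depth. Reports the fraction of truth sites classified specific
    to either pseudo-species.
    """
    config = synthetic.SimulationConfig(
        genome_length=genome_length, n_sites=n_sites, depth=depth,
        enrichment=enrichment, seed=seed)
    presence = np.tile([1, 1, 1, 1], (n_sites, 1))
    truth = synthetic.simulate_binding_history(config, presence=presence)
    reads = synthetic.simulate_chip_reads(truth, config, species=("mel",))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))

    def resplit(frames):
        pool = pd.concat(frames, ignore_index=True)
        perm = rng.permutation(len(pool))
        k = len(pool) // len(frames)
        return [pool.iloc[perm[i * k:(i + 1) * k]].reset_index(drop=True)
                for i in range(len(frames))]

    chip = _frames(reads, "mel", "chip", config.n_replicates)
    inp = _frames(reads, "mel", "input", config.n_replicates)
    result = divergence.analyze_pair(chip, inp, resplit(chip), resplit(inp),
                                     config.genome_length, seed=seed)
    labels = divergence.assign_site_classes(result["classified"],
                                            truth.summits)
    specific = np.isin(labels, ["reference_specific", "other_specific"])
    return {"fpr": float(specific.mean()), "n_sites": n_sites,
            "labels": labels, "threshold": result["threshold"]}
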