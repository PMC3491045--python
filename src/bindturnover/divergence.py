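"""Reference-centric cross-species binding divergence classification.

Reads from the non-reference species are translated into reference
coordinates through the orthology map, the twelve samples of a species pair
(2 species x ChIP/input x replicates) are normalized to a common density
mass, and an ANOVA-like linear categorical model

    Y = B0 + B_E*Experiment + B_S*Species + B_I*(Experiment x Species) + e

is fitted at every coordinate. Experiment is 1 for ChIP, Species is 1 for
the reference species, so B_E + B_I is the reference ChIP enrichment,
B_E the non-reference enrichment, and B_I the species-specific ChIP effect.
Smoothed enrichment and -log10 p tracks are then thresholded to classify
each candidate region as shared, reference-specific, other-specific or
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import DensityTrack

#: -log10 p reported when the residual variance is exactly zero
LOGP_CAP = 350.0

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# read translation
# ---------------------------------------------------------------------------

def _translation_keep_mask(starts, orthology_map, read_length, min_match):
    mask = orthology_map.mappable_mask()
    if starts.max() + read_length > len(mask) or starts.min() < 0:
        raise ValueError("read outside the orthology map's source chromosome")
    cum = np.concatenate([[0], np.cumsum(mask)])
    mapped = cum[starts + read_length] - cum[starts]
    return (mapped / read_length) >= min_match


def translate_reads(read_starts, orthology_map, read_length: int = 36,
                    min_match: float = 0.5):
    """Translate reads into reference coordinates via the orthology map.

    A read survives when at least ``min_match`` of its bases fall in
    mappable intervals of the map; the toy maps are coordinate-identity on
    mappable windows, so surviving reads keep their coordinates. Returns
    ``(surviving starts, n_dropped)``.
    """
    starts = np.asarray(read_starts, dtype=int)
    if starts.size == 0:
        return starts, 0
    keep = _translation_keep_mask(starts, orthology_map, read_length, min_match)
    return starts[keep], int((~keep).sum())


def translate_read_frame(reads: "pd.DataFrame", orthology_map,
                         read_length: int = 36, min_match: float = 0.5):
    """Frame-level translation preserving strand columns."""
    if reads.empty:
        return reads, 0
    keep = _translation_keep_mask(reads["start"].to_numpy(), orthology_map,
                                  read_length, min_match)
    return reads[keep].reset_index(drop=True), int((~keep).sum())


# ---------------------------------------------------------------------------
# pair normalization
# ---------------------------------------------------------------------------

def pair_normalize(tracks: list[DensityTrack]):
    """Scale every sample's total density mass to the pair minimum.

    Idempotent: a second application is the identity.
    """
    masses = np.array([t.values.sum() for t in tracks])
    if np.any(masses <= 0):
        raise ValueError("cannot pair-normalize a zero-mass sample")
    target = masses.min()
    factors = target / masses
    scaled = [dc_replace(t, values=t.values * f)
              for t, f in zip(tracks, factors)]
    return scaled, factors.tolist()


# ---------------------------------------------------------------------------
# the linear categorical model
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """OLS fit of the 2x2 (experiment x species) categorical model at one
    coordinate. Reference coding: the intercept is the non-reference input
    cell mean."""

    b0: float
    b_e: float          # ChIP effect in the non-reference species
    b_s: float          # species effect among input samples
    b_i: float          # interaction: reference ChIP diff minus other ChIP diff
    sigma2: float       # residual variance (df = N - 4)
    enrichment_ref: float
    enrichment_other: float
    p_chip_ref: float
    p_chip_other: float
    p_interaction: float
    zero_variance: bool = False


def _logp_from_z(z, sigma2_zero, estimate):
    """-log10 two-sided normal p; capped where residual variance is zero."""
    logp = -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / _LN10
    logp = np.where(sigma2_zero, np.where(estimate != 0, LOGP_CAP, 0.0), logp)
    return np.minimum(logp, LOGP_CAP)


def fit_pair_tracks(chip_ref, input_ref, chip_other, input_other) -> dict:
    """Vectorized per-coordinate fit of the categorical model.

    Each argument is a (replicates, L) array of normalized CDP values. The
    balanced 2x2 design makes ordinary least squares identical to cell-mean
    contrasts; coefficient p-values use the large-sample normal
    approximation (see the methods note). Returns per-coordinate tracks of
    the two species' ChIP enrichment estimates, the interaction estimate,
    and their -log10 p values.
    """
    cells = [np.atleast_2d(np.asarray(a, dtype=float))
             for a in (chip_ref, input_ref, chip_other, input_other)]
    r = cells[0].shape[0]
    if any(c.shape != cells[0].shape for c in cells) or r < 2:
        raise ValueError("balanced design with >=2 replicates per cell required")
    means = [c.mean(axis=0) for c in cells]
    m_cr, m_ir, m_co, m_io = means
    sse = sum(((c - m) ** 2).sum(axis=0) for c, m in zip(cells, means))
    df = 4 * r - 4
    sigma2 = sse / df
    zero = sigma2 <= 0
    s2 = np.where(zero, np.nan, sigma2)

    enr_ref = m_cr - m_ir
    enr_other = m_co - m_io
    interaction = enr_ref - enr_other
    se_diff = np.sqrt(s2 * 2.0 / r)
    se_int = np.sqrt(s2 * 4.0 / r)
    with np.errstate(invalid="ignore", divide="ignore"):
        logp_ref = _logp_from_z(enr_ref / se_diff, zero, enr_ref)
        logp_other = _logp_from_z(enr_other / se_diff, zero, enr_other)
        logp_int = _logp_from_z(interaction / se_int, zero, interaction)
    return {
        "enrichment_ref": enr_ref,
        "enrichment_other": enr_other,
        "interaction": interaction,
        "logp_chip_ref": logp_ref,
        "logp_chip_other": logp_other,
        "logp_interaction": logp_int,
        "sigma2": sigma2,
        "coefficients": {
            "b0": m_io, "b_e": enr_other, "b_s": m_ir - m_io, "b_i": interaction,
        },
    }


def fit_site_model(y, experiment, species) -> ModelFit:
    """Fit the categorical model to the observations at one coordinate.

    ``experiment`` is 1/True for ChIP, ``species`` is 1/True for the
    reference species; the design must be balanced with at least two
    replicates per cell.
    """
    y = np.asarray(y, dtype=float)
    e = np.asarray(experiment).astype(bool)
    s = np.asarray(species).astype(bool)
    cells = [y[e & s], y[~e & s], y[e & ~s], y[~e & ~s]]
    r = len(cells[0])
    if r < 2 or any(len(c) != r for c in cells):
        raise ValueError("balanced design with >=2 replicates per cell required")
    res = fit_pair_tracks(*(c[:, None] for c in cells))
    sigma2 = float(res["sigma2"][0])
    return ModelFit(
        b0=float(res["coefficients"]["b0"][0]),
        b_e=float(res["coefficients"]["b_e"][0]),
        b_s=float(res["coefficients"]["b_s"][0]),
        b_i=float(res["coefficients"]["b_i"][0]),
        sigma2=sigma2,
        enrichment_ref=float(res["enrichment_ref"][0]),
        enrichment_other=float(res["enrichment_other"][0]),
        p_chip_ref=float(10.0 ** -res["logp_chip_ref"][0]),
        p_chip_other=float(10.0 ** -res["logp_chip_other"][0]),
        p_interaction=float(10.0 ** -res["logp_interaction"][0]),
        zero_variance=bool(sigma2 <= 0),
    )


# ---------------------------------------------------------------------------
# smoothing and classification
# ---------------------------------------------------------------------------

def smooth_tracks(values: np.ndarray, window: int = 100, step: int = 1) -> np.ndarray:
    """Sliding-window moving average (window centred, step 1 by default).

    The window shrinks at chromosome ends: each output coordinate is the
    mean over the available coordinates, so output length equals input
    length. ``step`` > 1 subsamples the smoothed track.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    out = num / den
    return out[::step] if step > 1 else out


def union_regions(regions_a, regions_b, merge_gap: int = 100) -> list[tuple[int, int]]:
    """Merge two interval lists into unified candidate regions."""
    merged: list[list[int]] = []
    for s, e in sorted([tuple(r) for r in (*regions_a, *regions_b)]):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


def classify_site(region, tracks: dict, threshold: float = 0.4,
                  logp_cut: float = 20.0) -> dict:
    """Classify one candidate region from the smoothed model tracks.

    shared: both species' enrichment above the threshold and both
    ChIP/input comparisons significant. reference_specific: reference
    above, other below, reference ChIP/input significant and the
    species-specific ChIP effect (interaction) significant; symmetric for
    other_specific. Everything else is unclassified (conservative).
    """
    start, end = int(region[0]), int(region[1])
    if end <= start:
        raise ValueError("empty candidate region")
    sl = slice(start, end)
    combined = np.maximum(tracks["enrichment_ref"][sl],
                          tracks["enrichment_other"][sl])
    if combined.size == 0:
        raise ValueError("region has no fitted coordinates")
    summit = start + int(np.argmax(combined))
    enr_r = tracks["enrichment_ref"][summit]
    enr_o = tracks["enrichment_other"][summit]
    lp_r = tracks["logp_chip_ref"][summit]
    lp_o = tracks["logp_chip_other"][summit]
    lp_i = tracks["logp_interaction"][summit]
    if enr_r > threshold and enr_o > threshold and lp_r > logp_cut and lp_o > logp_cut:
        label = "shared"
    elif enr_r > threshold and enr_o <= threshold and lp_r > logp_cut and lp_i > logp_cut:
        label = "reference_specific"
    elif enr_o > threshold and enr_r <= threshold and lp_o > logp_cut and lp_i > logp_cut:
        label = "other_specific"
    else:
        label = "unclassified"
    return {
        "start": start, "end": end, "summit": summit, "class": label,
        "enrichment_ref": float(enr_r), "enrichment_other": float(enr_o),
        "logp_chip_ref": float(lp_r), "logp_chip_other": float(lp_o),
        "logp_interaction": float(lp_i),
    }


def classify_pair(chip_ref, input_ref, chip_other, input_other,
                  candidate_regions, threshold: float = 0.4,
                  logp_cut: float = 20.0, window: int = 100) -> pd.DataFrame:
    """Fit, smooth and classify every candidate region of one species pair.

    The four arguments are (replicates, L) arrays of pair-normalized CDP
    values; ``candidate_regions`` are reference-coordinate intervals
    (typically the union of the two species' peak calls).
    """
    fit = fit_pair_tracks(chip_ref, input_ref, chip_other, input_other)
    smoothed = {k: smooth_tracks(fit[k], window=window)
                for k in ("enrichment_ref", "enrichment_other", "interaction",
                          "logp_chip_ref", "logp_chip_other", "logp_interaction")}
    rows = [classify_site(region, smoothed, threshold, logp_cut)
            for region in candidate_regions]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# error rates and the direct comparison
# ---------------------------------------------------------------------------

def estimate_error_rates(truth_classes, called_classes) -> dict:
    """Classification error against known truth.

    FPR is the fraction of truly shared sites called specific to either
    species; FNR the fraction of truly diverged sites called shared; the
    unclassified fraction is reported separately (all as fractions).
    """
    truth = np.asarray(truth_classes)
    called = np.asarray(called_classes)
    if truth.shape != called.shape:
        raise ValueError("truth and calls must align")
    specific = np.isin(called, ["reference_specific", "other_specific"])
    shared_truth = truth == "shared"
    diverged_truth = ~shared_truth
    out = {"n_shared_truth": int(shared_truth.sum()),
           "n_diverged_truth": int(diverged_truth.sum()),
           "unclassified_fraction": float((called == "unclassified").mean())}
    out["fpr"] = (float(specific[shared_truth].mean())
                  if shared_truth.any() else np.nan)
    out["fnr"] = (float((called[diverged_truth] == "shared").mean())
                  if diverged_truth.any() else np.nan)
    out["total"] = out["fpr"] + out["fnr"] if shared_truth.any() and \
        diverged_truth.any() else np.nan
    return out


def _stack_tracks(read_frames, genome_length, bandwidth, shift, read_length,
                  role, species):
    from .peaks import compile_density
    return [compile_density(df["start"].to_numpy(), genome_length, bandwidth,
                            shift, strands=df["strand"].to_numpy(),
                            read_length=read_length, role=role,
                            species=species, replicate=i + 1)
            for i, df in enumerate(read_frames)]


def analyze_pair(ref_chip, ref_input, other_chip, other_input,
                 genome_length: int, orthology_map=None,
                 read_length: int = 36, min_match: float = 0.5,
                 bandwidth: float = 30.0, shift: int = 75,
                 threshold: float | None = None, logp_cut: float = 20.0,
                 window: int = 100, seed: int = 0) -> dict:
    """Full divergence analysis of one species pair.

    Inputs are per-replicate read frames (columns ``start``/``strand``);
    the non-reference reads are translated through ``orthology_map`` when
    one is given. Candidate regions are the union of the two species' own
    peak segmentations; classification uses the reference species'
    permutation threshold when ``threshold`` is None (the empirically
    determined default).
    Returns classification table, thresholds, candidates and drop counts.
    """
    from .peaks import (depth_normalize, enrichment_tracks,
                        permutation_threshold, segment_peaks)

    n_dropped = 0
    if orthology_map is not None:
        translated = []
        for df in [*other_chip, *other_input]:
            kept, dropped = translate_read_frame(df, orthology_map,
                                                 read_length, min_match)
            translated.append(kept)
            n_dropped += dropped
        other_chip = translated[:len(other_chip)]
        other_input = translated[len(other_chip):]

    tracks = {
        "chip_ref": _stack_tracks(ref_chip, genome_length, bandwidth, shift,
                                  read_length, "chip", "ref"),
        "input_ref": _stack_tracks(ref_input, genome_length, bandwidth, shift,
                                   read_length, "input", "ref"),
        "chip_other": _stack_tracks(other_chip, genome_length, bandwidth, shift,
                                    read_length, "chip", "other"),
        "input_other": _stack_tracks(other_input, genome_length, bandwidth,
                                     shift, read_length, "input", "other"),
    }
    flat = [t for group in tracks.values() for t in group]
    normalized, factors = pair_normalize(flat)
    it = iter(normalized)
    tracks = {k: [next(it) for _ in group] for k, group in tracks.items()}

    rng = np.random.default_rng(seed)
    thresholds, candidates = {}, {}
    for sp in ("ref", "other"):
        chip, inp = tracks[f"chip_{sp}"], tracks[f"input_{sp}"]
        thr = permutation_threshold(chip, inp, seed=rng)
        enr, fold = enrichment_tracks(chip, inp)
        segs = segment_peaks(enr, fold, thr)
        thresholds[sp] = thr
        candidates[sp] = [(p.start, p.end) for p in segs]
    regions = union_regions(candidates["ref"], candidates["other"])

    if threshold is None:
        threshold = thresholds["ref"]
    arr = {k: np.stack([t.values for t in tracks[k]]) for k in tracks}
    classified = classify_pair(arr["chip_ref"], arr["input_ref"],
                               arr["chip_other"], arr["input_other"],
                               regions, threshold=threshold,
                               logp_cut=logp_cut, window=window)
    return {"classified": classified, "threshold": float(threshold),
            "species_thresholds": thresholds, "candidates": regions,
            "dropped_reads": n_dropped,
            "normalization_factors": factors}


def assign_site_classes(classified: pd.DataFrame, summits,
                        max_distance: int = 250) -> list[str]:
    """Class label of the candidate region covering each site summit.

    A summit inside a region takes that region's class; otherwise the
    nearest region within ``max_distance`` bases is used; summits with no
    nearby region are unclassified (no candidate enrichment there).
    """
    labels = []
    if classified.empty:
        return ["unclassified"] * len(summits)
    starts = classified["start"].to_numpy()
    ends = classified["end"].to_numpy()
    mids = classified["summit"].to_numpy()
    cls = classified["class"].to_numpy()
    for summit in np.asarray(summits, dtype=int):
        inside = (starts <= summit) & (summit < ends)
        if inside.any():
            labels.append(cls[np.flatnonzero(inside)[0]])
            continue
        d = np.abs(mids - summit)
        labels.append(cls[d.argmin()] if d.min() <= max_distance
                      else "unclassified")
    return labels


def direct_region_overlap(peaks_ref, peaks_other_translated) -> float:
    """Pairwise conservation by direct region comparison.

    Fraction of reference peak intervals sharing at least 1 bp with any
    translated non-reference peak interval. Intervals are (start, end)
    half-open pairs.
    """
    ref = [tuple(map(int, r)) for r in peaks_ref]
    other = sorted(tuple(map(int, r)) for r in peaks_other_translated)
    if not ref:
        return 0.0
    starts = np.array([s for s, _ in other]) if other else np.empty(0, int)
    ends = np.array([e for _, e in other]) if other else np.empty(0, int)
    hit = 0
    for s, e in ref:
        if other and np.any((starts < e) & (ends > s)):
            hit += 1
    return hit / len(ref)
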