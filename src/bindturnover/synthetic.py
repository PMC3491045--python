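"""Synthetic-data generators with recorded ground truth.

Everything the comparative pipeline consumes can be produced here at toy
scale: a small annotated genome, binding-site histories from a two-state
gain/loss process on the fixed (((mel,sim),yak),pse) phylogeny, replicate
ChIP/input read sets, cross-species orthology maps with unmappable gaps,
multi-strain polymorphism panels with class-specific frequency spectra, and
replicate RNA-seq count tables coupled to binding divergence. Each
generator is deterministic under the configured seed, and every read,
variant and count traces back to a truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evolution import BRANCHES, SPECIES, SPLIT_TIMES
from .io import GFF3_COLUMNS

# stage tags mixed into the seed so generators draw independent streams
_STAGE = {"annotation": 1, "history": 2, "reads": 3, "orthology": 4,
          "polymorphism": 5, "expression": 6}


def _rng(config, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, _STAGE[stage])))


@dataclass
class SimulationConfig:
    """Study conditions for the toy comparative experiment.

    Replicate structure (3 ChIP + 3 input per species), read length (36 bp),
    the 4-species phylogeny with splits at 2.5/6/25 Myr and the 37-strain
    polymorphism panels mirror the real study design; genome size, depth and
    site count are desk-scale.
    """

    genome_length: int = 200_000
    chrom: str = "chr2T"
    n_genes: int = 50
    n_tes: int = 10
    n_sites: int = 200
    gain_rate: float = 0.02       # gains per site per Myr
    loss_rate: float = 0.04       # losses per site per Myr
    enrichment: float = 8.0       # summit density over the sample's background
    depth: int = 200_000          # reads per sample (exact)
    n_replicates: int = 3
    read_length: int = 36
    fragment_size: int = 150
    peak_sd: float = 60.0         # spread of fragment centers around a summit
    n_strains: int = 37
    theta: float = 0.01           # neutral population mutation rate per base
    divergence_factor: float = 8.0  # fixed differences per base = theta*factor
    alpha_true: dict = field(default_factory=lambda: {
        "neutral": 0.0, "synonymous": 0.0, "purifying": 0.0, "positive": 0.4})
    identity_decay: float = 0.0239   # per-Myr decay of orthologous identity
    identity_sd: float = 0.08
    unmappable_frac: float = 0.05    # at the deepest split; scales with time
    orthology_window: int = 500
    expr_dispersion: float = 0.1
    expr_log2fc: float = 4.0
    coupling_diverged: float = 0.5   # P(true expression change | diverged site)
    coupling_background: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("genome_length", "n_genes", "n_sites", "gain_rate",
                     "loss_rate", "enrichment", "depth", "n_replicates",
                     "n_strains", "theta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class TruthSet:
    """Ground truth for one simulated binding landscape."""

    summits: np.ndarray                 # reference summit coordinate per site
    presence: np.ndarray                # (n_sites, 4) over SPECIES
    origin_branch: list                 # true branch of most recent mel gain
    age_class: list
    event_log: pd.DataFrame             # branch/type per simulated transition

    def __post_init__(self):
        if len(self.presence) and not self.presence.any(axis=1).all():
            raise ValueError("presence vectors must never be all-zero")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_GENE_EXON1 = 100
_GENE_INTRON = 60     # < 65 bp: qualifies as a neutral small intron
_GENE_EXON2 = 150
_GENE_SPAN = _GENE_EXON1 + _GENE_INTRON + _GENE_EXON2
_TE_SPAN = 300


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Toy genome annotation: genes (exons + one small intron each) and TEs.

    Gene bodies never overlap; every gene carries one intron shorter than
    65 bp, whose 8th-30th nucleotides are the neutral small-intron windows
    used as the neutral reference class downstream.
    """
    span = config.n_genes * _GENE_SPAN + config.n_tes * _TE_SPAN
    if span and config.genome_length < 10 * span:
        raise ValueError(
            f"cannot pack {config.n_genes} genes + {config.n_tes} TEs into "
            f"{config.genome_length} bp (need genome >= 10x annotated span {span})")
    rng = _rng(config, "annotation")
    n_feat = config.n_genes + config.n_tes
    rows = []
    if n_feat:
        slot = config.genome_length // n_feat
        kinds = (["gene"] * config.n_genes) + (["te"] * config.n_tes)
        order = rng.permutation(n_feat)
        for i, idx in enumerate(order):
            kind = kinds[idx]
            width = _GENE_SPAN if kind == "gene" else _TE_SPAN
            lo = i * slot
            start = int(lo + rng.integers(0, max(1, slot - width)))
            if kind == "te":
                rows.append((config.chrom, "sim", "transposable_element", start,
                             start + _TE_SPAN, ".", "+", ".",
                             f"ID=TE{idx - config.n_genes:04d}"))
                continue
            gid = f"g{idx:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            parts = [("exon", start, start + _GENE_EXON1),
                     ("intron", start + _GENE_EXON1,
                      start + _GENE_EXON1 + _GENE_INTRON),
                     ("exon", start + _GENE_EXON1 + _GENE_INTRON,
                      start + _GENE_SPAN)]
            rows.append((config.chrom, "sim", "gene", start, start + _GENE_SPAN,
                         ".", strand, ".", f"ID={gid}"))
            for typ, s, e in parts:
                rows.append((config.chrom, "sim", typ, s, e, ".", strand, ".",
                             f"Parent={gid}"))
    df = pd.DataFrame(rows, columns=GFF3_COLUMNS)
    return df.sort_values(["start", "type"], kind="stable").reset_index(drop=True)


def small_intron_windows(annotation: pd.DataFrame) -> pd.DataFrame:
    """Neutral windows: the 8th-30th nucleotides of introns shorter than 65 bp."""
    introns = annotation[annotation["type"] == "intron"]
    short = introns[(introns["end"] - introns["start"]) < 65]
    out = short.copy()
    out["start"] = short["start"] + 7
    out["end"] = short["start"] + 30
    return out[["seqid", "start", "end", "strand", "attributes"]].reset_index(drop=True)


def gene_tss(annotation: pd.DataFrame) -> pd.DataFrame:
    genes = annotation[annotation["type"] == "gene"]
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    ids = [a.split("ID=")[1] for a in genes["attributes"]]
    return pd.DataFrame({"gene_id": ids, "tss": tss.astype(int)}
                        ).sort_values("gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# binding history on the phylogeny
# ---------------------------------------------------------------------------

def _evolve_branch(state, length, gain, loss, rng):
    """Gillespie walk of the 2-state chain along one branch; returns
    (end state, n_gains, n_losses)."""
    t, gains, losses = 0.0, 0, 0
    while True:
        rate = gain if state == 0 else loss
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= length:
            break
        if state == 0:
            state, gains = 1, gains + 1
        else:
            state, losses = 0, losses + 1
    return state, gains, losses


_NODE_ORDER = ("anc_msy", "pse", "anc_ms", "yak", "mel", "sim")  # parents first


def simulate_binding_history(config: SimulationConfig,
                             presence: np.ndarray | None = None) -> TruthSet:
    """Simulate per-site presence vectors by gain/loss on the phylogeny.

    Sites absent from every extant species are resampled (they would leave
    no observable event). When ``presence`` is given the stochastic process
    is skipped and only summits plus the implied truth columns are built —
    used for designed truth sets such as the half-shared/half-specific
    validation landscape.
    """
    rng = _rng(config, "history")
    n = config.n_sites
    summits = _place_summits(config, rng)
    if presence is not None:
        presence = np.asarray(presence, dtype=int)
        if presence.shape != (n, 4):
            raise ValueError("presence must be (n_sites, 4)")
        origin = [None] * n
        events = pd.DataFrame(columns=["site", "branch", "type", "count"])
        return TruthSet(summits, presence, origin, [None] * n, events)

    if config.gain_rate <= 0 or config.loss_rate < 0:
        raise ValueError("gain_rate must be > 0 and loss_rate >= 0")
    pi1 = config.gain_rate / (config.gain_rate + config.loss_rate)
    pres = np.zeros((n, 4), dtype=int)
    origin, ages, ev_rows = [], [], []
    for i in range(n):
        while True:
            states = {"root": int(rng.random() < pi1)}
            site_events = []
            gain_times = {}  # node -> whether lineage ends in a gained state
            for node in _NODE_ORDER:
                parent, _child, length = BRANCHES[node]
                s, g, l = _evolve_branch(states[parent], length,
                                         config.gain_rate, config.loss_rate, rng)
                states[node] = s
                if g:
                    site_events.append((i, node, "gain", g))
                if l:
                    site_events.append((i, node, "loss", l))
            vec = tuple(states[sp] for sp in SPECIES)
            if any(vec):
                break
        pres[i] = vec
        ev_rows.extend(site_events)
        br, age = _true_origin(states, site_events)
        origin.append(br)
        ages.append(age)
    events = pd.DataFrame(ev_rows, columns=["site", "branch", "type", "count"])
    return TruthSet(summits, pres, origin, ages, events)


def _true_origin(states, site_events):
    """True origin branch of the mel lineage presence (None if mel unbound).

    The origin is the branch carrying the most recent gain on the path
    root -> anc_msy -> anc_ms -> mel; presence inherited unchanged from the
    root maps to "root" (age >25 Myr)."""
    from .evolution import AGE_CLASS
    if states["mel"] == 0:
        return None, None
    gained = {e[1] for e in site_events if e[2] == "gain"}
    for node in ("mel", "anc_ms", "anc_msy"):
        if node in gained:
            origin = node
            break
    else:
        origin = "root"
    return origin, AGE_CLASS[origin]


def _place_summits(config, rng) -> np.ndarray:
    margin, min_sep = 400, 600
    usable = config.genome_length - 2 * margin - (config.n_sites - 1) * min_sep
    if usable <= 0:
        raise ValueError("genome too small for the requested site count")
    offsets = np.sort(rng.uniform(0, usable, size=config.n_sites))
    return (margin + offsets + min_sep * np.arange(config.n_sites)).astype(int)


# ---------------------------------------------------------------------------
# ChIP / input reads
# ---------------------------------------------------------------------------

def _effective_peak_width(config) -> float:
    return config.peak_sd * np.sqrt(2 * np.pi)


def expected_peak_reads_per_site(config, n_present: int) -> float:
    """Reads per present site such that summit density is ``enrichment``
    times the ChIP sample's own background, under the fixed total depth."""
    if n_present == 0:
        return 0.0
    w = _effective_peak_width(config)
    e1 = config.enrichment - 1.0
    return (e1 * w * config.depth) / (config.genome_length + n_present * e1 * w)


def _reads_frame(starts, strands, config, name):
    starts = np.clip(starts.astype(int), 0,
                     config.genome_length - config.read_length)
    return pd.DataFrame({
        "chrom": config.chrom, "start": starts,
        "end": starts + config.read_length,
        "name": name, "score": 0,
        "strand": np.where(strands, "+", "-"),
    })


def simulate_chip_reads(truth: TruthSet, config: SimulationConfig,
                        species=SPECIES) -> dict:
    """Per-sample read tables for every (species, ChIP/input, replicate).

    Input samples are homogeneous background. ChIP samples mix background
    with fragment-structured peak reads: fragment centers Gaussian around
    the summit (sd ``peak_sd``), read starts offset by half a fragment on
    the sequenced strand. Every sample emits exactly ``depth`` reads.
    """
    rng = _rng(config, "reads")
    out = {}
    half_frag = config.fragment_size // 2
    for sp_i, sp in enumerate(SPECIES):
        if sp not in species:
            continue
        present = truth.summits[truth.presence[:, sp_i] == 1]
        m = len(present)
        per_site = expected_peak_reads_per_site(config, m)
        p_peak = min(1.0, m * per_site / config.depth) if config.depth else 0.0
        if config.enrichment <= 1.0:
            p_peak = 0.0
        for rep in range(config.n_replicates):
            for role in ("chip", "input"):
                name = f"{sp}_{role}_{rep + 1}"
                if role == "input" or p_peak == 0.0:
                    starts = rng.uniform(0, config.genome_length, config.depth)
                    strands = rng.random(config.depth) < 0.5
                else:
                    n_peak = rng.binomial(config.depth, p_peak)
                    sites = present[rng.integers(0, m, n_peak)]
                    centers = sites + rng.normal(0, config.peak_sd, n_peak)
                    strands_pk = rng.random(n_peak) < 0.5
                    starts_pk = np.where(
                        strands_pk, centers - half_frag,
                        centers + half_frag - config.read_length)
                    n_bg = config.depth - n_peak
                    starts = np.concatenate(
                        [starts_pk, rng.uniform(0, config.genome_length, n_bg)])
                    strands = np.concatenate(
                        [strands_pk, rng.random(n_bg) < 0.5])
                out[(sp, role, rep + 1)] = _reads_frame(
                    np.asarray(starts), np.asarray(strands), config, name)
    return out


# ---------------------------------------------------------------------------
# orthology maps
# ---------------------------------------------------------------------------

@dataclass
class OrthologyMap:
    """Interval-level coordinate map between one species and the reference.

    The toy genomes share the reference coordinate system, so translation is
    the identity on mappable windows; windows flagged unmappable swallow the
    reads that fall in them, and per-window match fractions emulate partial
    alignability."""

    species: str
    genome_length: int
    windows: pd.DataFrame  # start, end, mappable, match_fraction, identity

    def mappable_mask(self) -> np.ndarray:
        mask = np.zeros(self.genome_length, dtype=bool)
        for _, w in self.windows.iterrows():
            if w["mappable"]:
                mask[int(w["start"]):int(w["end"])] = True
        return mask


def simulate_orthology(config: SimulationConfig, truth: TruthSet | None = None):
    """Orthology maps per non-reference species plus per-site identities.

    Window identity decays with divergence time (mean exp(-decay*t) with
    Gaussian scatter); the unmappable fraction grows linearly with time up
    to ``unmappable_frac`` at the deepest split. Returns
    ``(maps, site_identity)`` where ``site_identity`` is a DataFrame of
    per-site 201-bp window identities for each species pair (empty when no
    truth is supplied)."""
    rng = _rng(config, "orthology")
    win = config.orthology_window
    edges = np.arange(0, config.genome_length + win, win)
    maps = {}
    ident_rows = {}
    for sp, t in SPLIT_TIMES.items():
        mean_ident = float(np.exp(-config.identity_decay * t))
        n_win = len(edges) - 1
        ident = np.clip(rng.normal(mean_ident, config.identity_sd, n_win), 0, 1)
        p_unmap = config.unmappable_frac * t / max(SPLIT_TIMES.values())
        mappable = rng.random(n_win) >= p_unmap
        match = np.where(mappable, np.clip(ident + 0.2, 0, 1), 0.0)
        windows = pd.DataFrame({
            "start": edges[:-1].clip(max=config.genome_length),
            "end": edges[1:].clip(max=config.genome_length),
            "mappable": mappable, "match_fraction": match, "identity": ident,
        })
        maps[sp] = OrthologyMap(sp, config.genome_length, windows)
        if truth is not None:
            ident_rows[sp] = np.clip(
                rng.normal(mean_ident, config.identity_sd, len(truth.summits)),
                0, 1)
    site_identity = pd.DataFrame(ident_rows)
    if truth is not None and len(site_identity):
        site_identity.insert(0, "summit", truth.summits)
    return maps, site_identity


# ---------------------------------------------------------------------------
# polymorphism panels
# ---------------------------------------------------------------------------

#: per-class generator knobs: (constraint on new mutations, SFS skew exponent)
CLASS_PARAMS = {
    "neutral": (1.0, 1.0),
    "synonymous": (1.0, 1.0),
    "purifying": (0.35, 1.8),
    "positive": (0.6, 1.2),
}

_BASES = np.array(list("ACGT"))
_A1_CACHE: dict[int, float] = {}


def _a1(n: int) -> float:
    if n not in _A1_CACHE:
        _A1_CACHE[n] = float(np.sum(1.0 / np.arange(1, n)))
    return _A1_CACHE[n]


def simulate_polymorphism(config: SimulationConfig, site_class: str = "neutral",
                          n_loci: int = 20, locus_length: int = 200,
                          rng: np.random.Generator | None = None) -> list[dict]:
    """Strain panels + outgroup for one site class.

    Neutral classes draw derived-allele counts from the equilibrium spectrum
    (mass proportional to 1/i); purifying classes skew the spectrum toward
    rare variants (1/i**skew) and thin both polymorphism and divergence by
    the constraint factor; positive classes inflate fixed differences so the
    true adaptive fraction equals ``alpha_true`` for the class.
    """
    if config.n_strains < 4:
        raise ValueError("need at least 4 strains")
    if site_class not in CLASS_PARAMS:
        raise ValueError(f"unknown site class {site_class!r}")
    if rng is None:
        rng = _rng(config, "polymorphism")
    constraint, skew = CLASS_PARAMS[site_class]
    alpha = config.alpha_true.get(site_class, 0.0)
    n = config.n_strains
    i_vals = np.arange(1, n)
    sfs_w = (1.0 / i_vals ** skew)
    sfs_w /= sfs_w.sum()
    panels = []
    for locus in range(n_loci):
        anc = _BASES[rng.integers(0, 4, locus_length)]
        strains = np.tile(anc, (n, 1)).copy()
        exp_s = config.theta * locus_length * _a1(n) * constraint
        s_count = rng.poisson(exp_s)
        positions = rng.choice(locus_length, size=min(s_count, locus_length),
                               replace=False)
        for pos in positions:
            derived = _BASES[(np.flatnonzero(_BASES == anc[pos])[0]
                              + rng.integers(1, 4)) % 4]
            carriers = rng.choice(n, size=rng.choice(i_vals, p=sfs_w),
                                  replace=False)
            strains[carriers, pos] = derived
        out_seq = anc.copy()
        exp_d = config.theta * locus_length * config.divergence_factor * constraint
        exp_d /= max(1e-9, 1.0 - alpha)
        d_count = rng.poisson(exp_d)
        free = np.setdiff1d(np.arange(locus_length), positions)
        d_pos = rng.choice(free, size=min(d_count, len(free)), replace=False)
        for pos in d_pos:
            out_seq[pos] = _BASES[(np.flatnonzero(_BASES == anc[pos])[0]
                                   + rng.integers(1, 4)) % 4]
        quality = np.full((n, locus_length), 40, dtype=int)
        panels.append({
            "locus": f"{site_class}_{locus:03d}",
            "site_class": site_class,
            "strains": {f"strain{j + 1:02d}": "".join(strains[j])
                        for j in range(n)},
            "outgroup": "".join(out_seq),
            "quality": quality,
            "truth": {"n_segregating": len(positions), "n_fixed": len(d_pos),
                      "alpha_true": alpha},
        })
    return panels


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_expression(truth: TruthSet, config: SimulationConfig,
                        annotation: pd.DataFrame, pair_species: str = "sim"):
    """Replicate count tables for mel vs one other species.

    Genes whose nearest binding site diverged between the pair receive a
    true between-species fold change with probability ``coupling_diverged``;
    other genes with probability ``coupling_background``. Counts are
    negative binomial around lognormal baselines. Returns
    ``(counts, gene_truth)``.
    """
    if config.expr_dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _rng(config, "expression")
    tss = gene_tss(annotation)
    sp_i = SPECIES.index(pair_species)
    diverged_site = truth.presence[:, 0] != truth.presence[:, sp_i]
    near = np.abs(tss["tss"].to_numpy()[:, None]
                  - truth.summits[None, :]).argmin(axis=1)
    coupled = diverged_site[near]
    p_change = np.where(coupled, config.coupling_diverged,
                        config.coupling_background)
    true_div = rng.random(len(tss)) < p_change
    base = rng.lognormal(np.log(100), 1.0, len(tss))
    fc = np.where(true_div, 2.0 ** (config.expr_log2fc
                                    * np.where(rng.random(len(tss)) < 0.5, 1, -1)),
                  1.0)
    r = 1.0 / config.expr_dispersion
    cols = {}
    for sp, mean in (("mel", base), (pair_species, base * fc)):
        for rep in range(config.n_replicates):
            lam = rng.gamma(r, mean / r)
            cols[f"{sp}_rep{rep + 1}"] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=tss["gene_id"]).rename_axis("gene_id")
    gene_truth = pd.DataFrame({
        "gene_id": tss["gene_id"],
        "nearest_site": near,
        "near_diverged_site": coupled,
        "true_expression_diverged": true_div,
    })
    return counts, gene_truth
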