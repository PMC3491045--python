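"""Selection statistics on binding-associated DNA.

Operates on aligned strain panels (one locus = n strain sequences plus an
outgroup sequence and a per-base quality mask): Tajima's D from the folded
frequency spectrum summary, McDonald-Kreitman contingency counts, the
simple and shared (multilocus maximum-likelihood) adaptive fraction alpha,
and the multilocus HKA test with a coalescent-simulated null (msprime).
Masked bases are excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class PolymorphismPanel:
    locus: str
    strains: dict                      # name -> sequence (equal lengths)
    outgroup: str
    quality: np.ndarray | None = None  # (n_strains, length) Phred scores
    site_class: str = ""

    def __post_init__(self):
        lengths = {len(s) for s in self.strains.values()} | {len(self.outgroup)}
        if len(lengths) != 1:
            raise ValueError("all sequences in a panel must have equal length")

    @property
    def n(self) -> int:
        return len(self.strains)

    @property
    def length(self) -> int:
        return len(self.outgroup)

    def matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.strains.values()])


@dataclass
class MKCounts:
    p_sel: int
    p_neu: int
    d_sel: int
    d_neu: int

    def __post_init__(self):
        if min(self.p_sel, self.p_neu, self.d_sel, self.d_neu) < 0:
            raise ValueError("MK counts must be non-negative")


@dataclass
class SelectionEstimate:
    alpha: float
    ci_low: float
    ci_high: float
    method: str
    log_likelihood: float = np.nan
    n_loci: int = 0
    details: dict = field(default_factory=dict)


def mask_panel(panel: PolymorphismPanel, phred_floor: int = 30):
    """Replace strain bases below the Phred floor with N.

    Returns ``(masked panel, masked fraction)``.
    """
    if panel.quality is None:
        return panel, 0.0
    mat = panel.matrix()
    low = panel.quality < phred_floor
    mat[low] = "N"
    masked = PolymorphismPanel(
        locus=panel.locus,
        strains={name: "".join(row) for name, row
                 in zip(panel.strains, mat)},
        outgroup=panel.outgroup,
        quality=panel.quality,
        site_class=panel.site_class,
    )
    return masked, float(low.mean())


def _clean_columns(panel: PolymorphismPanel, with_outgroup: bool = False):
    """Alignment columns with no masked/ambiguous base in any used sequence."""
    mat = panel.matrix()
    ok = ~np.any(np.isin(mat, ["N", "n", "-"]), axis=0)
    if with_outgroup:
        out = np.array(list(panel.outgroup))
        ok &= ~np.isin(out, ["N", "n", "-"])
        return mat[:, ok], out[ok]
    return mat[:, ok]


def _tajima_constants(n: int) -> dict:
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d(panel: PolymorphismPanel) -> float:
    """Tajima's D: (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    pi is the mean number of pairwise differences over clean columns, S the
    number of segregating sites. Requires >=4 sequences and >=1
    segregating site (D is undefined at S=0 and raising beats silently
    reporting 0).
    """
    if panel.n < 4:
        raise ValueError("need at least 4 sequences")
    mat = _clean_columns(panel)
    n = panel.n
    seg = np.array([len(set(col)) > 1 for col in mat.T])
    s_count = int(seg.sum())
    if s_count == 0:
        raise ValueError("Tajima's D undefined with no segregating sites")
    pi = 0.0
    for col in mat[:, seg].T:
        _, counts = np.unique(col, return_counts=True)
        pi += (n * (n - 1) / 2 - np.sum(counts * (counts - 1) / 2))
    pi /= n * (n - 1) / 2
    k = _tajima_constants(n)
    var = k["e1"] * s_count + k["e2"] * s_count * (s_count - 1)
    return float((pi - s_count / k["a1"]) / np.sqrt(var))


def _fixed_and_polymorphic(panel: PolymorphismPanel):
    """Counts of polymorphic and fixed sites against the outgroup.

    A segregating site is polymorphic regardless of the outgroup state
    (standard MK precedence); a fixed difference is monomorphic in the
    panel and different from the outgroup.
    """
    mat, out = _clean_columns(panel, with_outgroup=True)
    poly = fixed = 0
    for col, o in zip(mat.T, out):
        alleles = set(col)
        if len(alleles) > 1:
            poly += 1
        elif col[0] != o:
            fixed += 1
    return poly, fixed


def mk_table(panel_sel: PolymorphismPanel, panel_neu: PolymorphismPanel) -> dict:
    """McDonald-Kreitman 2x2 counts and the independence test.

    Chi-square on (polymorphic, fixed) x (selected, neutral); replaced by
    Fisher's exact test (flagged) when any table marginal is zero.
    """
    p_sel, d_sel = _fixed_and_polymorphic(panel_sel)
    p_neu, d_neu = _fixed_and_polymorphic(panel_neu)
    counts = MKCounts(p_sel=p_sel, p_neu=p_neu, d_sel=d_sel, d_neu=d_neu)
    table = np.array([[p_sel, d_sel], [p_neu, d_neu]])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        _, p = stats.fisher_exact(table)
        return {"counts": counts, "p_value": float(p), "test": "fisher",
                "statistic": np.nan}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"counts": counts, "p_value": float(p), "test": "chi2",
            "statistic": float(chi2)}


def alpha_simple(counts: MKCounts) -> float:
    """Classical adaptive fraction: alpha = 1 - (D_neu*P_sel)/(D_sel*P_neu)."""
    if counts.d_sel == 0 or counts.p_neu == 0:
        raise ValueError("alpha undefined: D_sel and P_neu must be positive")
    return 1.0 - (counts.d_neu * counts.p_sel) / (counts.d_sel * counts.p_neu)


# ---------------------------------------------------------------------------
# shared alpha (multilocus maximum likelihood)
# ---------------------------------------------------------------------------

def _locus_profile_ll(counts: MKCounts, alpha: float) -> float:
    """Max over the locus nuisance ratio f of the binomial log-likelihood.

    Model: P_sel | P_tot ~ Bin(f/(1+f)); D_sel | D_tot ~ Bin(g/(1+g)) with
    g = f/(1-alpha). f absorbs the locus's relative mutational target and
    constraint; alpha is shared across loci. Binomial constants are omitted
    (they cancel in every likelihood comparison over alpha).
    """
    ps, pn = counts.p_sel, counts.p_neu
    ds, dn = counts.d_sel, counts.d_neu
    c = 1.0 / (1.0 - alpha)

    def nll(log_f):
        f = np.exp(log_f)
        g = f * c
        lp = np.log(f / (1 + f))
        l1p = -np.log1p(f)
        lq = np.log(g / (1 + g))
        l1q = -np.log1p(g)
        return -(ps * lp + pn * l1p + ds * lq + dn * l1q)

    res = optimize.minimize_scalar(nll, bounds=(-12, 12), method="bounded",
                                   options={"xatol": 1e-7})
    return -res.fun


def shared_alpha(loci: list[MKCounts], n_boot: int = 1000, seed: int = 0,
                 alpha_grid=None, use_bootstrap: bool = False) -> SelectionEstimate:
    """Shared adaptive fraction over loci with locus-specific neutral ratios.

    Maximum likelihood with a single alpha shared across loci; the 95%
    confidence interval comes from the profile likelihood (chi-square(1)
    cutoff), optionally cross-checked by a bootstrap over loci. For a
    single locus the estimate reduces to the classical ``alpha_simple``
    identity. Degenerate loci (no neutral polymorphism or divergence at
    all) are dropped with a record in the result details.
    """
    usable = [c for c in loci
              if (c.p_sel + c.p_neu) > 0 and (c.d_sel + c.d_neu) > 0]
    dropped = len(loci) - len(usable)
    if len(usable) < 1:
        raise ValueError("no usable loci")
    if alpha_grid is None:
        alpha_grid = np.linspace(-4.0, 0.98, 250)

    profile = np.array([sum(_locus_profile_ll(c, a) for c in usable)
                        for a in alpha_grid])
    best = int(np.argmax(profile))
    # local refinement around the grid optimum
    lo = alpha_grid[max(best - 1, 0)]
    hi = alpha_grid[min(best + 1, len(alpha_grid) - 1)]
    res = optimize.minimize_scalar(
        lambda a: -sum(_locus_profile_ll(c, a) for c in usable),
        bounds=(lo, hi), method="bounded")
    alpha_hat, ll_max = float(res.x), -float(res.fun)

    cutoff = ll_max - stats.chi2.ppf(0.95, 1) / 2.0
    inside = profile >= cutoff
    ci_low = float(alpha_grid[inside].min()) if inside.any() else float(alpha_grid[0])
    ci_high = float(alpha_grid[inside].max()) if inside.any() else float(alpha_grid[-1])
    ci_low, ci_high = min(ci_low, alpha_hat), max(ci_high, alpha_hat)

    details = {"dropped_loci": dropped}
    if use_bootstrap:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            sample = [usable[i] for i in rng.integers(0, len(usable), len(usable))]
            bres = optimize.minimize_scalar(
                lambda a: -sum(_locus_profile_ll(c, a) for c in sample),
                bounds=(-4.0, 0.98), method="bounded")
            boots.append(float(bres.x))
        details["bootstrap_ci"] = (float(np.percentile(boots, 2.5)),
                                   float(np.percentile(boots, 97.5)))
    return SelectionEstimate(alpha=alpha_hat, ci_low=ci_low, ci_high=ci_high,
                             method="shared-ML", log_likelihood=ll_max,
                             n_loci=len(usable), details=details)


# ---------------------------------------------------------------------------
# multilocus HKA
# ---------------------------------------------------------------------------

def _a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def _b2(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


def _hka_fit(s_counts, d_counts, sample_sizes):
    """Jointly estimate per-locus theta and the divergence time T.

    Moment system: theta_i = (S_i + D_i)/(a1(n_i) + T + 1) and
    sum(D) = (T + 1) * sum(theta).
    """
    a = np.array([_a1(n) for n in sample_sizes], dtype=float)
    s = np.asarray(s_counts, dtype=float)
    d = np.asarray(d_counts, dtype=float)

    def gap(t):
        theta = (s + d) / (a + t + 1.0)
        return d.sum() - (t + 1.0) * theta.sum()

    lo, hi = 1e-9, 1e9
    if gap(lo) < 0:          # divergence so low the best T is ~0
        t_hat = lo
    else:
        t_hat = optimize.brentq(gap, lo, hi)
    theta = (s + d) / (a + t_hat + 1.0)
    return theta, t_hat


def _hka_statistic(s_counts, d_counts, sample_sizes):
    theta, t_hat = _hka_fit(s_counts, d_counts, sample_sizes)
    a = np.array([_a1(n) for n in sample_sizes])
    b = np.array([_b2(n) for n in sample_sizes])
    exp_s = theta * a
    var_s = exp_s + (theta ** 2) * b
    exp_d = theta * (t_hat + 1.0)
    var_d = exp_d + theta ** 2
    dev = ((np.asarray(s_counts) - exp_s) ** 2 / var_s
           + (np.asarray(d_counts) - exp_d) ** 2 / var_d)
    return float(dev.sum()), theta, t_hat, dev


def hka_multilocus(loci: list[dict], n_sims: int = 1000, seed: int = 0) -> dict:
    """Multilocus HKA test with a coalescent-simulated null distribution.

    Each locus supplies ``S`` (segregating sites in the panel), ``D``
    (fixed differences to the outgroup) and ``n`` (sample size). The
    deviation statistic sums squared standardized deviations of S and D
    from their jointly fitted neutral expectations; the p-value is the
    fraction of msprime-simulated null datasets (at the fitted theta and
    T, re-fitted per dataset) whose statistic is at least as large.
    """
    import msprime

    if len(loci) < 2:
        raise ValueError("HKA needs at least two loci")
    s_obs = [int(l["S"]) for l in loci]
    d_obs = [int(l["D"]) for l in loci]
    ns = [int(l["n"]) for l in loci]
    stat_obs, theta, t_hat, dev = _hka_statistic(s_obs, d_obs, ns)

    demography = msprime.Demography()
    demography.add_population(name="A", initial_size=1.0)
    demography.add_population(name="B", initial_size=1.0)
    demography.add_population(name="anc", initial_size=1.0)
    demography.add_population_split(time=max(t_hat, 1e-6), derived=["A", "B"],
                                    ancestral="anc")
    rng = np.random.default_rng(seed)
    stats_null = np.empty(n_sims)
    for k in range(n_sims):
        s_sim, d_sim = [], []
        for theta_i, n_i in zip(theta, ns):
            ts = msprime.sim_ancestry(
                samples={"A": n_i, "B": 1}, demography=demography,
                ploidy=1, sequence_length=1,
                random_seed=int(rng.integers(1, 2 ** 31 - 1)))
            mts = msprime.sim_mutations(
                ts, rate=theta_i / 2.0, discrete_genome=False,
                random_seed=int(rng.integers(1, 2 ** 31 - 1)))
            geno = mts.genotype_matrix()      # (sites, samples)
            a_part = geno[:, :n_i]
            b_seq = geno[:, n_i]
            seg = np.array([len(set(row)) > 1 for row in a_part], dtype=bool) \
                if len(a_part) else np.zeros(0, bool)
            s_sim.append(int(seg.sum()))
            pick = a_part[:, rng.integers(0, n_i)] if len(a_part) else b_seq
            d_sim.append(int(np.sum(pick != b_seq)))
        stats_null[k], *_ = _hka_statistic(s_sim, d_sim, ns)
    p = float(np.mean(stats_null >= stat_obs))
    return {"statistic": stat_obs, "p_value": p, "theta": theta.tolist(),
            "t_divergence": t_hat, "per_locus_deviation": dev.tolist(),
            "n_sims": n_sims}


def panels_to_mk_loci(selected_panels, neutral_panels) -> list[MKCounts]:
    """Pair selected/neutral panels by index into per-locus MK counts."""
    loci = []
    for sel, neu in zip(selected_panels, neutral_panels):
        p_sel, d_sel = _fixed_and_polymorphic(sel)
        p_neu, d_neu = _fixed_and_polymorphic(neu)
        loci.append(MKCounts(p_sel=p_sel, p_neu=p_neu, d_sel=d_sel, d_neu=d_neu))
    return loci


def panel_from_dict(d: dict) -> PolymorphismPanel:
    """Adapter from the synthetic generator's panel records."""
    return PolymorphismPanel(locus=d["locus"], strains=d["strains"],
                             outgroup=d["outgroup"],
                             quality=d.get("quality"),
                             site_class=d.get("site_class", ""))
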