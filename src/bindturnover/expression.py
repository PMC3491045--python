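"""Expression divergence and its association with binding-site classes.

Replicate RNA-seq count tables for a species pair are upper-quartile
normalized; between-species divergence per gene is called by a
likelihood-ratio test of the species effect in a count GLM (negative
binomial with method-of-moments dispersion, Poisson when underdispersed)
with a Benjamini-Hochberg adjusted p < 0.01 and |log2 fold change| > 2.
Association tests link gene status to the evolutionary class of the
nearest binding site; the congruence test compares new genes against
resampled old-gene pools; TE overlap contrasts site classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

READ_FLOOR = 5  # genes with fewer total mapped reads are NA


def normalize_and_filter(counts: pd.DataFrame) -> dict:
    """Upper-quartile normalization factors and the NA filter.

    The scaling factor of each sample is (geometric mean of all samples'
    upper quartiles) / (its own upper quartile), computed over genes with
    any reads; genes with fewer than 5 reads in total are marked NA.
    Returns {"counts", "factors", "na"}.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample")
    expressed = counts[counts.sum(axis=1) > 0]
    uq = expressed.apply(lambda c: np.percentile(c, 75), axis=0)
    if (uq <= 0).any():
        uq = uq.clip(lower=uq[uq > 0].min())
    ref = float(np.exp(np.mean(np.log(uq))))
    factors = ref / uq
    na = counts.sum(axis=1) < READ_FLOOR
    return {"counts": counts, "factors": factors, "na": na}


def _nb_loglik(y, mu, alpha):
    if alpha <= 0:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    r = 1.0 / alpha
    return float(np.sum(stats.nbinom.logpmf(y, r, r / (r + mu))))


def _group_mle_mu(y, exposure, alpha, tol=1e-8):
    """MLE of a common mean with per-sample exposures for NB/Poisson.

    For Poisson this is sum(y)/sum(exposure); for NB it is found by a few
    Newton steps (the likelihood in log-mu is smooth and unimodal).
    """
    mu0 = max(y.sum() / exposure.sum(), 1e-8)
    if alpha <= 0:
        return mu0
    log_mu = np.log(mu0)
    r = 1.0 / alpha
    for _ in range(50):
        mu = np.exp(log_mu) * exposure
        w = (y - mu) * r / (r + mu)
        grad = np.sum(w)
        hess = -np.sum(r * mu * (r + y) / (r + mu) ** 2)
        if abs(hess) < 1e-12:
            break
        step = grad / hess
        log_mu -= np.clip(step, -2, 2)
        if abs(step) < tol:
            break
    return float(np.exp(log_mu))


def call_divergence(table: dict, species_of_sample: dict,
                    adj_p: float = 0.01, log2fc: float = 2.0,
                    family: str = "nb") -> pd.DataFrame:
    """Per-gene between-species divergence calls.

    ``table`` is the output of :func:`normalize_and_filter`;
    ``species_of_sample`` maps column names to the two species labels.
    A gene is ``diverged`` when the BH-adjusted LRT p-value is below
    ``adj_p`` and |log2 fold change| exceeds ``log2fc``; NA genes keep
    status NA.
    """
    counts, factors, na = table["counts"], table["factors"], table["na"]
    samples = list(counts.columns)
    species = np.array([species_of_sample[c] for c in samples])
    labels = pd.unique(species)
    if len(labels) != 2:
        raise ValueError("need exactly two species")
    group = species == labels[0]
    if group.sum() < 2 or (~group).sum() < 2:
        raise ValueError("need >=2 replicates per species")
    exposure = (1.0 / factors.to_numpy())  # larger library -> larger exposure
    y_all = counts.to_numpy(dtype=float)
    norm = y_all * factors.to_numpy()[None, :]

    pvals, fcs = np.full(len(counts), np.nan), np.full(len(counts), np.nan)
    for i in range(len(counts)):
        if na.iloc[i]:
            continue
        y = y_all[i]
        m = norm[i]
        m1, m2 = m[group].mean(), m[~group].mean()
        fcs[i] = np.log2((m1 + 0.5) / (m2 + 0.5))
        alpha = 0.0
        if family == "nb":
            # method-of-moments dispersion pooled over the two groups
            within_var = (m[group].var(ddof=1) + m[~group].var(ddof=1)) / 2
            mean_ = (m1 + m2) / 2
            alpha = max(0.0, (within_var - mean_) / max(mean_ ** 2, 1e-8))
        mu0 = _group_mle_mu(y, exposure, alpha)
        ll0 = _nb_loglik(y, mu0 * exposure, alpha)
        mu1 = _group_mle_mu(y[group], exposure[group], alpha)
        mu2 = _group_mle_mu(y[~group], exposure[~group], alpha)
        ll1 = (_nb_loglik(y[group], mu1 * exposure[group], alpha)
               + _nb_loglik(y[~group], mu2 * exposure[~group], alpha))
        lrt = max(0.0, 2.0 * (ll1 - ll0))
        pvals[i] = stats.chi2.sf(lrt, df=1)

    tested = ~np.isnan(pvals)
    adj = np.full(len(counts), np.nan)
    if tested.any():
        adj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    status = np.where(na, "NA",
                      np.where((adj < adj_p) & (np.abs(fcs) > log2fc),
                               "diverged", "stable"))
    return pd.DataFrame({
        "gene_id": counts.index, "p_value": pvals, "adj_p": adj,
        "log2_fold_change": fcs, "status": status,
    }).set_index("gene_id")


def nearest_gene(summits, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene (by summit-to-TSS distance) for each site.

    Ties break to the lexicographically smaller gene id, making the link
    deterministic.
    """
    if tss_table.empty:
        raise ValueError("empty annotation")
    tss_sorted = tss_table.sort_values(["tss", "gene_id"]).reset_index(drop=True)
    tss = tss_sorted["tss"].to_numpy()
    genes = tss_sorted["gene_id"].to_numpy()
    rows = []
    for site_id, summit in enumerate(np.asarray(summits, dtype=int)):
        dist = np.abs(tss - summit)
        best = dist.min()
        cand = genes[dist == best]
        rows.append({"site_id": site_id, "gene_id": min(cand),
                     "distance": int(best)})
    return pd.DataFrame(rows)


def association_test(links: pd.DataFrame, statuses: pd.Series,
                     site_classes: pd.Series, class_a: str, class_b: str) -> dict:
    """One-sided Fisher test: diverged-expression enrichment near class_a.

    Genes are de-duplicated within a class (the union of nearest genes);
    NA genes are excluded. The alternative is that class_a genes are
    enriched for diverged expression relative to class_b.
    """
    table = []
    props = {}
    for cls in (class_a, class_b):
        sites = links[site_classes.loc[links["site_id"]].to_numpy() == cls]
        genes = pd.unique(sites["gene_id"])
        st = statuses.reindex(genes).dropna()
        st = st[st != "NA"]
        if st.empty:
            return {"skipped": True, "reason": f"no genes for class {cls!r}"}
        k = int((st == "diverged").sum())
        table.append([k, len(st) - k])
        props[cls] = k / len(st)
    _, p = stats.fisher_exact(table, alternative="greater")
    return {"skipped": False, "proportions": props, "table": table,
            "fisher_p": float(p)}


def congruence_test(new_gene_links, old_gene_links, flank_lengths,
                    n_resample: int = 1000, pool_size: int = 42,
                    seed: int = 0) -> dict:
    """Phylogenetic congruence of binding-site birth with gene birth.

    ``*_gene_links`` map each gene to the distance of its nearest
    phylogenetically congruent binding event (a site whose occupancy
    pattern matches the gene's origination pattern exactly), ``np.inf``
    when none exists. Returns the cumulative proportion curves (new genes,
    and the mean over ``n_resample`` draws of ``pool_size`` old genes), and
    a two-sample KS test between the new-gene distances and the old pool.
    """
    new_d = np.asarray(new_gene_links, dtype=float)
    old_d = np.asarray(old_gene_links, dtype=float)
    if len(old_d) < pool_size:
        raise ValueError("old-gene pool smaller than the resampling size")
    flanks = np.asarray(sorted(flank_lengths), dtype=float)
    new_curve = [(new_d <= f).mean() for f in flanks]
    rng = np.random.default_rng(seed)
    resampled = np.empty((n_resample, len(flanks)))
    for k in range(n_resample):
        pick = old_d[rng.choice(len(old_d), pool_size, replace=False)]
        resampled[k] = [(pick <= f).mean() for f in flanks]
    ks = stats.ks_2samp(new_d, old_d)
    return {"flanks": flanks.tolist(), "new_curve": new_curve,
            "old_curve_mean": resampled.mean(axis=0).tolist(),
            "ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue)}


def te_overlap(site_windows, te_intervals, site_classes,
               class_a: str, class_b: str) -> dict:
    """TE overlap (>=1 bp of the 201-bp site window) contrasted by class."""
    tes = sorted(tuple(map(int, t)) for t in te_intervals)
    starts = np.array([s for s, _ in tes]) if tes else np.empty(0, int)
    ends = np.array([e for _, e in tes]) if tes else np.empty(0, int)
    classes = np.asarray(site_classes)
    overlap = np.array([
        bool(len(tes)) and bool(np.any((starts < e) & (ends > s)))
        for s, e in site_windows])
    out = {"skipped": False}
    table = []
    for cls in (class_a, class_b):
        sel = classes == cls
        k, n = int(overlap[sel].sum()), int(sel.sum())
        out[cls] = {"overlapping": k, "total": n,
                    "percent": 100.0 * k / n if n else np.nan}
        table.append([k, n - k])
    if not len(tes) or not all(r[0] + r[1] for r in table):
        out["skipped"] = True
        return out
    _, p = stats.fisher_exact(table)
    out["fisher_p"] = float(p)
    return out


def summit_windows(summits, half_width: int = 100):
    """The 201-bp windows (summit +/- 100 bp) used for TE and popgen classes."""
    s = np.asarray(summits, dtype=int)
    return list(zip(s - half_width, s + half_width + 1))
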