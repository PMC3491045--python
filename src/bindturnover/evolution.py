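"""Evolutionary analysis of binding events on the fixed 4-taxon phylogeny.

The species quartet is D. melanogaster (mel), D. simulans (sim),
D. yakuba (yak) and D. pseudoobscura (pse), with topology
(((mel,sim),yak),pse) and split times 2.5, 6 and 25 Myr before present.
Each binding event carries a 4-bit occupancy vector over the quartet
(1 = bound in that species); this vector is the binary character on which
small-parsimony dating and gain/loss counting operate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

SPECIES = ("mel", "sim", "yak", "pse")
SPLIT_TIMES = {"sim": 2.5, "yak": 6.0, "pse": 25.0}

#: branch name -> (parent node, child node, length in Myr). Node times:
#: leaves 0, anc_ms 2.5, anc_msy 6, root 25.
BRANCHES = {
    "mel": ("anc_ms", "mel", 2.5),
    "sim": ("anc_ms", "sim", 2.5),
    "anc_ms": ("anc_msy", "anc_ms", 3.5),
    "yak": ("anc_msy", "yak", 6.0),
    "anc_msy": ("root", "anc_msy", 19.0),
    "pse": ("root", "pse", 25.0),
}

#: origin branch on the mel lineage -> age class of a mel binding site
AGE_CLASS = {
    "mel": "<2.5",
    "anc_ms": "2.5-6",
    "anc_msy": "6-25",
    "root": ">25",
}

_INTERNAL = ("anc_ms", "anc_msy", "root")
_MEL_PATH = ("root", "anc_msy", "anc_ms", "mel")  # nodes from root to the mel leaf


@dataclass(frozen=True)
class Phylogeny:
    """The immutable study phylogeny."""

    species: tuple[str, ...] = SPECIES
    split_times: tuple[float, float, float] = (2.5, 6.0, 25.0)


@dataclass
class ParsimonyResult:
    occupancy: tuple[int, int, int, int]
    n_events: int
    ambiguous: bool
    age_class: str | None          # None when the event is absent in mel
    origin_branch: str | None      # branch of the most recent mel-lineage gain
    gains: dict[str, int]          # per-branch gain counts (first MPR if tied)
    losses: dict[str, int]
    reconstructions: list[dict] = field(default_factory=list)


def enumerate_categories() -> list[tuple[int, int, int, int]]:
    """All 15 possible occupancy patterns over (mel, sim, yak, pse).

    Every pattern except all-absent, ordered from fully shared (1,1,1,1)
    down to pse-only (0,0,0,1); the all-zero vector is excluded because an
    event absent everywhere is not an event.
    """
    patterns = [p for p in itertools.product((1, 0), repeat=4) if any(p)]
    return patterns


def _reconstruction_events(occ, internal_states):
    """Per-branch (gains, losses) for one assignment of internal states."""
    state = dict(zip(SPECIES, occ))
    state.update(dict(zip(_INTERNAL, internal_states)))
    state["root"] = internal_states[2]
    gains, losses = {}, {}
    for name, (parent, child, _len) in BRANCHES.items():
        p, c = state[parent], state[child]
        if p == 0 and c == 1:
            gains[name] = 1
        elif p == 1 and c == 0:
            losses[name] = 1
    return gains, losses, state


def _origin_branch(state: dict[str, int]) -> str | None:
    """Most recent 0->1 transition on the root..mel path (None if mel unbound)."""
    if state["mel"] == 0:
        return None
    origin = "root"
    for parent, child in zip(_MEL_PATH[:-1], _MEL_PATH[1:]):
        if state[parent] == 0 and state[child] == 1:
            origin = child  # the branch leading into `child`
    # presence all the way from the root means inherited from the common ancestor
    if all(state[n] == 1 for n in _MEL_PATH):
        origin = "root"
    return origin


def parsimony_age(occupancy, tree: Phylogeny | None = None) -> ParsimonyResult:
    """Fitch small-parsimony dating of one occupancy vector.

    All 8 assignments of presence/absence to the three internal nodes are
    enumerated; reconstructions with the minimal number of state changes are
    retained. The event is flagged ambiguous when the most-parsimonious
    reconstructions disagree (in events or in the inferred origin branch).
    """
    occ = tuple(int(x) for x in occupancy)
    if len(occ) != 4 or not any(occ):
        raise ValueError("occupancy must be a non-zero 4-bit vector over "
                         f"{SPECIES}")
    best: list[dict] = []
    best_n = 99
    for internal in itertools.product((0, 1), repeat=3):
        gains, losses, state = _reconstruction_events(occ, internal)
        n = len(gains) + len(losses)
        rec = {"gains": gains, "losses": losses,
               "origin": _origin_branch(state), "n_events": n}
        if n < best_n:
            best, best_n = [rec], n
        elif n == best_n:
            best.append(rec)
    ambiguous = len(best) > 1
    first = best[0]
    origins = {r["origin"] for r in best}
    origin = first["origin"] if len(origins) == 1 else None
    return ParsimonyResult(
        occupancy=occ,
        n_events=best_n,
        ambiguous=ambiguous,
        age_class=(AGE_CLASS[origin] if origin is not None else
                   ("ambiguous" if occ[0] == 1 else None)),
        origin_branch=origin,
        gains=first["gains"],
        losses=first["losses"],
        reconstructions=best,
    )


def branch_turnover(results: list[ParsimonyResult]) -> dict:
    """Per-branch gain/loss counts over unambiguous events.

    Ambiguous events (ties among most-parsimonious reconstructions) are not
    folded into the headline per-branch counts — any tie-break would bias the
    gain/loss asymmetry — and are tallied separately.
    """
    gains = {b: 0 for b in BRANCHES}
    losses = {b: 0 for b in BRANCHES}
    n_ambiguous = 0
    total_events = 0
    for res in results:
        total_events += res.n_events
        if res.ambiguous:
            n_ambiguous += 1
            continue
        for b, k in res.gains.items():
            gains[b] += k
        for b, k in res.losses.items():
            losses[b] += k
    return {"gains": gains, "losses": losses, "n_ambiguous": n_ambiguous,
            "total_events": total_events}


def orthology_class(pair_identities: dict[str, float], cutoff: float = 0.5):
    """TWOB/FWOB flags from per-pair sequence identities of the 201-bp window.

    ``pair_identities`` maps the non-reference species name to the fractional
    identity of the mel-vs-that-species alignment. A pair is Two-Way
    Orthologous (TWOB) when identity is strictly greater than ``cutoff``;
    Four-Way Orthologous (FWOB) requires all three pairs to qualify. A
    missing alignment fails the comparison (no-orthology).
    """
    twob = {}
    for sp in ("sim", "yak", "pse"):
        ident = pair_identities.get(sp)
        twob[sp] = bool(ident is not None and ident > cutoff)
    return {"twob": twob, "fwob": all(twob.values())}


def divergence_rate_regression(divergence_percents, times):
    """OLS regression of pairwise binding divergence (%) on split time (Myr).

    Returns slope in % per Myr, the intercept, R-squared and the slope
    t-test p-value — the turnover-rate estimate of the comparative design.
    """
    times = np.asarray(times, dtype=float)
    div = np.asarray(divergence_percents, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two (time, divergence) points")
    fit = stats.linregress(times, div)
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.rvalue ** 2,
        "p_value": fit.pvalue,
    }


def per_myr_rate(count: float, myr: float) -> tuple[float, int]:
    """Events per Myr: exact rate plus the rounded headline integer.

    Rounding is half-away-from-zero (89/2.5 -> 35.6 -> 36).
    """
    if myr <= 0:
        raise ValueError("myr must be positive")
    rate = count / myr
    headline = int(np.floor(rate + 0.5)) if rate >= 0 else int(np.ceil(rate - 0.5))
    return rate, headline
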