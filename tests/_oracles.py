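"""Independent reference implementations shared across test modules."""

import itertools

import numpy as np

from bindturnover.popgen import PolymorphismPanel


def make_panel(seqs, outgroup=None, quality=None, locus="L"):
    return PolymorphismPanel(
        locus=locus,
        strains={f"s{i}": s for i, s in enumerate(seqs)},
        outgroup=outgroup or seqs[0],
        quality=quality)


def reference_tajimas_d(seqs):
    """From-scratch Tajima's D with explicit pairwise loops."""
    n = len(seqs)
    length = len(seqs[0])
    S = sum(len({s[j] for s in seqs}) > 1 for j in range(length))
    pi = 0.0
    for a, b in itertools.combinations(range(n), 2):
        pi += sum(seqs[a][j] != seqs[b][j] for j in range(length))
    pi /= n * (n - 1) / 2
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def random_panel(rng, n=None, length=None):
    n = n or int(rng.integers(5, 15))
    length = length or int(rng.integers(40, 120))
    bases = np.array(list("ACGT"))
    anc = bases[rng.integers(0, 4, length)]
    seqs = np.tile(anc, (n, 1))
    n_mut = int(rng.integers(1, 12))
    for _ in range(n_mut):
        pos = int(rng.integers(0, length))
        carriers = rng.choice(n, size=int(rng.integers(1, n)), replace=False)
        seqs[carriers, pos] = bases[(np.flatnonzero(bases == anc[pos])[0] + 1) % 4]
    return ["".join(row) for row in seqs]
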