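"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately naive: direct enumeration and textbook
formulas, sharing no code with the implementation paths they check.
"""

import math

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq):
    return "".join(COMP[b] for b in reversed(seq))


def nw_edit_distance(a, b):
    """Plain unit-cost Needleman-Wunsch edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def pam_matches(observed, patterns):
    return any(len(observed) == len(p)
               and all(o in IUPAC_SETS[c] for o, c in zip(observed, p))
               for p in patterns)


def enumerate_protospacer(window, guide):
    """All valid placements as (bulges, mism, start, end, strand, desc).

    Explicit string surgery per candidate: every placement x {no bulge,
    each interior RNA-bulge (delete spacer base 1..L-2), each interior
    DNA-bulge (skip the genomic base at gap 1..L-1)} on both strands,
    window coordinates on the forward strand.
    """
    spacer = guide.spacer
    L = len(spacer)
    W = len(window)
    out = []

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    for strand in "+-":
        seq = window if strand == "+" else rc(window)
        for i in range(W):
            # no bulge
            if i + L + 3 <= W:
                site = seq[i:i + L]
                m = ham(site, spacer)
                if m <= guide.max_mismatches and \
                        pam_matches(seq[i + L:i + L + 3], guide.pam_patterns):
                    out.append((0, m, i, i + L, strand, None))
            if guide.max_bulge < 1:
                continue
            # RNA bulge: spacer base b deleted, genomic footprint L-1
            if i + L - 1 + 3 <= W:
                site = seq[i:i + L - 1]
                for b in range(1, L - 1):
                    m = ham(site, spacer[:b] + spacer[b + 1:])
                    if m <= guide.max_mismatches and pam_matches(
                            seq[i + L - 1:i + L + 2], guide.pam_patterns):
                        out.append((1, m, i, i + L - 1, strand, ("RNA", b)))
            # DNA bulge: genomic base at gap b skipped, footprint L+1
            if i + L + 1 + 3 <= W:
                site = seq[i:i + L + 1]
                for b in range(1, L):
                    m = ham(site[:b] + site[b + 1:], spacer)
                    if m <= guide.max_mismatches and pam_matches(
                            seq[i + L + 1:i + L + 4], guide.pam_patterns):
                        out.append((1, m, i, i + L + 1, strand, ("DNA", b)))
    return out


def best_protospacer(window, guide):
    """Optimal placement under the documented tie-break, or None."""
    W = len(window)
    cands = enumerate_protospacer(window, guide)
    best_key, best = None, None
    for bulges, m, i, j, strand, desc in cands:
        if strand == "+":
            start, end = i, j
        else:
            start, end = W - j, W - i
        dist = abs((start + end) / 2 - W / 2)
        key = (bulges, m, dist, start, 0 if strand == "+" else 1)
        if best_key is None or key < best_key:
            best_key = key
            best = (bulges, m, start, end, strand, desc)
    return best


def bh_stepup(pvals):
    """Textbook BH: p_(i) * m / i with monotonicity from the largest down."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def welch_t(x, y):
    """Welch's t statistic, Welch-Satterthwaite df and two-sided p."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x, float), np.asarray(y, float)
    v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (len(x) - 1) + v2 ** 2 / (len(y) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def pearson_with_t_p(x, y):
    """Pearson r and the two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    r = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    t = r * math.sqrt((n - 2) / (1 - r ** 2))
    return r, 2 * tdist.sf(abs(t), n - 2)


def binom_ci(k_frac, n, alpha=0.01):
    """Exact (Clopper-Pearson) interval for a planted proportion."""
    from scipy.stats import beta
    k = k_frac * n
    lo = beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return lo, hi
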