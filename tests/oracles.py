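"""Independent brute-force oracles used by the test suite.

Each oracle is a direct, literal transcription of the rule it checks,
written without reference to the package implementation (no shared
helpers, no optimisations), so agreement is meaningful.
"""

import itertools

import numpy as np
from scipy.stats import hypergeom

_CHROM_SPECIAL = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}


def _ckey(c):
    c = str(c)
    if c.lower().startswith("chr"):
        c = c[3:]
    return (int(c), "") if c.isdigit() else (_CHROM_SPECIAL.get(c.upper(), 99), c.upper())


def brute_prune(snps, r2_of, r2_max, window_bp):
    """Greedy windowed pruning: keep a SNP iff r2 with every previously kept
    SNP on the same chromosome within the window is < r2_max.

    ``snps``: list of (snp_id, chrom, pos); ``r2_of(a, b)``: pairwise r2.
    """
    ordered = sorted(snps, key=lambda s: (*_ckey(s[1]), s[2]))
    kept = []
    for sid, c, p in ordered:
        ok = True
        for ksid, kc, kp in kept:
            if kc == c and abs(p - kp) <= window_bp and r2_of(sid, ksid) >= r2_max:
                ok = False
        if ok:
            kept.append((sid, c, p))
    return [s for s, _, _ in kept]


def brute_clump(snps, r2_of, lead_p_max, clump_r2_max, window_bp):
    """Greedy clumping over a sorted p list.

    ``snps``: list of (snp_id, chrom, pos, p_min).  Candidates with
    p < lead_p_max in ascending p (ties by chrom, pos); each unclaimed
    candidate leads and claims unclaimed same-chromosome SNPs within the
    window at r2 > clump_r2_max.  Returns [(lead, [members...]), ...].
    """
    order = sorted(snps, key=lambda s: (s[3], *_ckey(s[1]), s[2]))
    by_pos = sorted(snps, key=lambda s: s[2])  # members listed in position order
    claimed = set()
    out = []
    for sid, c, p, pv in order:
        if pv >= lead_p_max or sid in claimed:
            continue
        claimed.add(sid)
        members = []
        for osid, oc, op, opv in by_pos:
            if osid in claimed or oc != c or abs(op - p) > window_bp:
                continue
            if r2_of(sid, osid) > clump_r2_max:
                claimed.add(osid)
                members.append(osid)
        out.append((sid, members))
    return out


def fisher_p_enumeration(table):
    """Two-sided Fisher exact p by explicit hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def best_assignment_total_abs_r(Sa, Sb):
    """Max over all permutations of sum |Pearson r| between paired rows."""
    Ka, Kb = Sa.shape[0], Sb.shape[0]
    assert Ka <= Kb
    C = np.zeros((Ka, Kb))
    for i in range(Ka):
        for j in range(Kb):
            C[i, j] = abs(np.corrcoef(Sa[i], Sb[j])[0, 1])
    best = -1.0
    for perm in itertools.permutations(range(Kb), Ka):
        best = max(best, sum(C[i, perm[i]] for i in range(Ka)))
    return best


def m_eff_eigen(R):
    """Li-Ji-family effective test count from a correlation matrix."""
    lam = np.linalg.eigvalsh(np.asarray(R, float))
    return R.shape[0] - float(np.sum((lam - 1.0)[lam > 1.0]))
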