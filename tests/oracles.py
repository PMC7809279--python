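"""Independent brute-force oracles used to cross-check the package.

These deliberately reimplement each quantity from its definition, in the
most literal way possible, and share no code with barcodekit.
"""

from itertools import combinations
from math import log

BASES = set("ACGT")


def classify_columns(rows):
    """Literal per-column classification: returns dict of counts."""
    out = {"conserved": 0, "variable": 0, "parsimony_informative": 0,
           "singleton": 0, "considered": 0}
    for col in zip(*rows):
        obs = [c for c in col if c in BASES]
        if len(obs) < 2:
            continue
        out["considered"] += 1
        distinct = sorted(set(obs))
        if len(distinct) == 1:
            out["conserved"] += 1
            continue
        out["variable"] += 1
        duplicated = [b for b in distinct if obs.count(b) >= 2]
        if len(duplicated) >= 2:
            out["parsimony_informative"] += 1
        elif len(distinct) == 2 and min(obs.count(b) for b in distinct) == 1:
            out["singleton"] += 1
    return out


def pair_frequency_tally(rows, frame_offset=0):
    """Exhaustive pair-and-column enumeration of ii/si/sv per codon position."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    keys = ["avg", "pos1", "pos2", "pos3"]
    ii = dict.fromkeys(keys, 0.0)
    si = dict.fromkeys(keys, 0.0)
    sv = dict.fromkeys(keys, 0.0)
    pairs = list(combinations(rows, 2))
    for a, b in pairs:
        for j, (x, y) in enumerate(zip(a, b)):
            if x not in BASES or y not in BASES:
                continue
            pk = f"pos{((j - frame_offset) % 3) + 1}"
            target = ii if x == y else (si if (x, y) in transitions else sv)
            target["avg"] += 1
            target[pk] += 1
    n = len(pairs)
    return ({k: v / n for k, v in ii.items()},
            {k: v / n for k, v in si.items()},
            {k: v / n for k, v in sv.items()})


def substitution_tally(a, b):
    """Per-column substitution typing for one pair: (L_eff, ts, tv)."""
    transitions = {frozenset("AG"), frozenset("CT")}
    L = ts = tv = 0
    for x, y in zip(a, b):
        if x in BASES and y in BASES:
            L += 1
            if x != y:
                if frozenset((x, y)) in transitions:
                    ts += 1
                else:
                    tv += 1
    return L, ts, tv


def tajima_d_from_scratch(n, S, k):
    """Recompute Tajima's D by writing out every coefficient."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k - S / a1) / (e1 * S + e2 * S * (S - 1)) ** 0.5


def stirling_unsigned(n):
    """Explicit integer table |S1(n, j)|, j = 0..n."""
    row = [1] + [0] * n
    for m in range(n):
        new = [0] * (n + 1)
        for j in range(n + 1):
            new[j] = m * row[j] + (row[j - 1] if j > 0 else 0)
        row = new
    return row


def fu_fs_from_ewens(n, k_obs, theta):
    """Fu's Fs via explicit Ewens probabilities (exact integers + floats)."""
    s1 = stirling_unsigned(n)
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    probs = [s1[j] * theta**j / rising for j in range(n + 1)]
    sp = sum(probs[k_obs:])
    return log(sp / (1.0 - sp))


def pairwise_hamming_histogram(rows):
    """Exhaustive pairwise difference counts."""
    diffs = [sum(1 for x, y in zip(a, b) if x != y)
             for a, b in combinations(rows, 2)]
    top = max(diffs)
    hist = [0.0] * (top + 1)
    for d in diffs:
        hist[d] += 1
    return [h / len(diffs) for h in hist], diffs


def random_additive_tree(rng, n_leaves, lo=0.01, hi=1.0):
    """Random unrooted binary tree with branch lengths in [lo, hi].

    Returns (labels, distance dict {(a, b): d} with a < b, splits), where
    splits is the set of internal bipartitions, each a frozenset of the
    two frozensets of leaf names.
    """
    labels = [f"T{i}" for i in range(n_leaves)]
    all_leaves = frozenset(labels)
    # component: dict leaf -> distance to the component's junction point
    comps = [{lab: 0.0} for lab in labels]
    dists = {}
    splits = set()

    def record_cross(a, b, extra):
        for la, da in a.items():
            for lb, db in b.items():
                key = (la, lb) if la < lb else (lb, la)
                dists[key] = da + db + extra

    while len(comps) > 2:
        i, j = sorted(rng.choice(len(comps), size=2, replace=False))
        b, a = comps.pop(int(j)), comps.pop(int(i))
        ea, eb = rng.uniform(lo, hi), rng.uniform(lo, hi)
        record_cross(a, b, ea + eb)
        # the two new edges split off leaves(a) and leaves(b) respectively
        for side_leaves in (frozenset(a), frozenset(b)):
            if 2 <= len(side_leaves) <= n_leaves - 2:
                splits.add(frozenset([side_leaves, all_leaves - side_leaves]))
        merged = {k: v + ea for k, v in a.items()}
        merged.update({k: v + eb for k, v in b.items()})
        comps.append(merged)
    a, b = comps
    e = rng.uniform(lo, hi)
    record_cross(a, b, e)
    side = frozenset(a)
    if 2 <= len(side) <= n_leaves - 2:
        splits.add(frozenset([side, all_leaves - side]))
    return labels, dists, splits
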