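"""Independent brute-force oracles used to check the package implementations.

Everything here is deliberately naive (per-base boolean arrays, forward
scans, exhaustive enumeration) and shares no code with the package.
"""

from itertools import combinations

import numpy as np


# --- per-base coverage oracle for the interval algebra ----------------------

def coverage_array(intervals, genome):
    """dict chrom -> boolean per-base coverage array."""
    cov = {c: np.zeros(n, dtype=bool) for c, n in genome.items()}
    for iv in intervals:
        cov[iv.chrom][iv.start : iv.end] = True
    return cov


def runs(cov):
    """(chrom, start, end) maximal covered runs of a coverage dict."""
    out = []
    for chrom in sorted(cov):
        arr = cov[chrom]
        i = 0
        while i < len(arr):
            if arr[i]:
                j = i
                while j < len(arr) and arr[j]:
                    j += 1
                out.append((chrom, i, j))
                i = j
            else:
                i += 1
    return out


def oracle_overlap_any(query, subject, genome):
    cov = coverage_array(subject, genome)
    return [bool(cov[iv.chrom][iv.start : iv.end].any()) for iv in query]


def oracle_subtract(peaks, control, genome):
    """Indices of peaks kept under whole-peak removal on any base overlap."""
    keep = oracle_overlap_any(peaks, control, genome)
    return [i for i, hit in enumerate(keep) if not hit]


# --- trajectory classifier oracle -------------------------------------------

def oracle_classify(pattern):
    """Module code for one boolean (start, mid..., end) open pattern.

    Forward scan: try each start position of a maintained endpoint-state
    suffix, earliest wins.
    """
    start, *mid, end = pattern
    if start and end:
        return "PO"
    if not start and not end:
        return "NE"
    base = "OC" if start else "CO"
    traj = list(mid) + [end]
    for t in range(1, len(traj) + 1):
        if all(x == end for x in traj[t - 1 :]):
            return f"{base}{t}"
    raise AssertionError("unreachable: final element equals the endpoint state")


def oracle_agreement_probability(true_pattern, flip_p):
    """Exact P(classifier label survives independent per-call flips)."""
    true_label = oracle_classify(true_pattern)
    n = len(true_pattern)
    total = 0.0
    for mask in range(2 ** n):
        bits = [(mask >> i) & 1 for i in range(n)]
        flipped = tuple(s ^ b for s, b in zip(true_pattern, bits))
        weight = flip_p ** sum(bits) * (1 - flip_p) ** (n - sum(bits))
        if oracle_classify(flipped) == true_label:
            total += weight
    return total


# --- cross-system category oracle -------------------------------------------

def oracle_category(directions, systems):
    """Nested-if reimplementation of the cross-system truth table."""
    assert len(directions) == len(systems)
    if any(d == "excluded" for d in directions):
        return "discordant"
    has_up = any(d == "up" for d in directions)
    has_down = any(d == "down" for d in directions)
    if has_up and has_down:
        return "discordant"
    if not has_up and not has_down:
        return "none"
    tag = "up" if has_up else "down"
    hits = [s for s, d in zip(systems, directions) if d == tag]
    if len(hits) == len(systems):
        return f"common_{tag}"
    if len(hits) == 1:
        return f"specific_{tag}:{hits[0]}"
    return f"pair_{tag}:{'+'.join(hits)}"


# --- hypergeometric enumeration oracle --------------------------------------

def oracle_hypergeom_upper(universe_size, n_successes, n_draws, k):
    """P(X >= k) by exhaustively enumerating every possible draw."""
    population = range(universe_size)
    successes = set(range(n_successes))
    hits = 0
    total = 0
    for draw in combinations(population, n_draws):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


# --- random interval generation ---------------------------------------------

def random_intervals(rng, genome, n_max=30, factory=None):
    """Random (possibly overlapping) intervals on a small genome."""
    from chromodyn import GenomicInterval

    make = factory or GenomicInterval
    out = []
    chroms = list(genome)
    for _ in range(int(rng.integers(0, n_max + 1))):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = genome[chrom]
        start = int(rng.integers(0, size - 1))
        end = int(rng.integers(start + 1, min(start + 1 + size // 4, size) + 1))
        out.append(make(chrom, start, end))
    return out
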