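import numpy as np
import pytest

from sirnaclust.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, small dataset for plumbing-level tests."""
    cfg = SimulationConfig(
        seed=7,
        n_chroms=1,
        chrom_length=400_000,
        n_genes=12,
        n_planted_clusters=6,
        background_rate=2.0,
        n_contaminant_reads=20,
    )
    return simulate_dataset(cfg)


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of the implementation's helpers)
# ---------------------------------------------------------------------------

def kdist_bruteforce(positions, k):
    """All-pairs k-th nearest neighbour distances, sorted descending."""
    pos = np.asarray(positions, float)
    out = []
    for i, p in enumerate(pos):
        d = np.sort(np.abs(np.delete(pos, i) - p))
        out.append(d[k - 1])
    return np.sort(np.array(out))[::-1]


def dbscan_bruteforce(starts, epsilon, minpts):
    """Reference DBSCAN over 1-D points; labels numbered by genomic order
    of each cluster's leftmost core point, border points joining the
    cluster of the leftmost core point within epsilon."""
    s = np.asarray(starts, float)
    n = len(s)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    dist = np.abs(s[:, None] - s[None, :])
    neighbors = dist <= epsilon
    core = neighbors.sum(axis=1) >= minpts
    comp = np.full(n, -1, dtype=int)
    # connected components of core points under epsilon-reachability (BFS)
    cid = 0
    for i in np.argsort(s, kind="stable"):
        if not core[i] or comp[i] != -1:
            continue
        stack = [i]
        comp[i] = cid
        while stack:
            j = stack.pop()
            for m in np.flatnonzero(neighbors[j] & core):
                if comp[m] == -1:
                    comp[m] = cid
                    stack.append(m)
        cid += 1
    labels[core] = comp[core]
    for i in np.flatnonzero(~core):
        reach = np.flatnonzero(neighbors[i] & core)
        if len(reach):
            leftmost = reach[np.lexsort((reach, s[reach]))[0]]
            labels[i] = comp[leftmost]
    return labels


def overlap_bruteforce(intervals, query):
    return [
        iv
        for iv in intervals
        if iv.chrom == query.chrom and iv.start < query.end and query.start < iv.end
    ]


def merge_bruteforce(intervals):
    """Interval union by sweep over sorted endpoints (>=1 bp overlap)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out = []
    for iv in ivs:
        if out and out[-1][0] == iv.chrom and iv.start < out[-1][2]:
            out[-1][2] = max(out[-1][2], iv.end)
        else:
            out.append([iv.chrom, iv.start, iv.end])
    return [tuple(x) for x in out]
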