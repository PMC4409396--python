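"""Independent brute-force oracles used by the test suite.

These deliberately use the simplest possible O(n^2) formulations so they
stay independent of the implementation paths they check.
"""

import numpy as np


def nn_keep_bruteforce(xy, threshold):
    """Indices kept by the NN pre-filter, via explicit pairwise distances."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    keep = []
    for i in range(n):
        best = np.inf
        for j in range(n):
            if i == j:
                continue
            d = np.sqrt((xy[i, 0] - xy[j, 0]) ** 2 + (xy[i, 1] - xy[j, 1]) ** 2)
            best = min(best, d)
        if best <= threshold:
            keep.append(i)
    return keep


def link_bruteforce(frames, xs, ys, photons, link_radius, photon_weighted=True):
    """Frame-by-frame greedy linker; returns the partition of event indices.

    Rule: open tracks (in creation order) each claim the nearest unclaimed
    event of the next frame within the link radius (ties -> lower event
    index); unclaimed events open new tracks; a track with no continuation
    in the very next frame closes.
    """
    tracks = []  # list of dicts: members, open
    for f in sorted(set(int(v) for v in frames)):
        for t in tracks:
            if t["open"] and t["last"] < f - 1:
                t["open"] = False
        idxs = [i for i in range(len(frames)) if frames[i] == f]
        claimed = set()
        for t in tracks:
            if not t["open"] or t["last"] != f - 1:
                continue
            w = np.array([photons[m] if photon_weighted else 1.0 for m in t["members"]])
            cx = np.average([xs[m] for m in t["members"]], weights=w)
            cy = np.average([ys[m] for m in t["members"]], weights=w)
            best, best_d = None, np.inf
            for i in idxs:
                if i in claimed:
                    continue
                d = np.hypot(xs[i] - cx, ys[i] - cy)
                if d <= link_radius and d < best_d:
                    best, best_d = i, d
            if best is not None:
                t["members"].append(best)
                t["last"] = f
                claimed.add(best)
        for i in idxs:
            if i not in claimed:
                tracks.append({"members": [i], "last": f, "open": True})
    return {frozenset(t["members"]) for t in tracks}


def bin_index_bruteforce(x, y, x0, y0, b):
    """Half-open histogram bin of a single point."""
    return int(np.floor((x - x0) / b)), int(np.floor((y - y0) / b))
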