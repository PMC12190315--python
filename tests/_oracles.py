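"""Independent brute-force references used to cross-check the package.

These are deliberately written in plain Python, structured differently from
the library implementations, and share only the documented conventions
(consecutive-interval initiation, inclusive boundaries, no retro-joining).
"""

from __future__ import annotations


def brute_force_segment(onsets, init_n=3, init_ili_max=1.0, term_gap=3.0):
    """Reference bout segmentation.

    Enumerates every candidate initiation index, picks the earliest viable
    one at or after the cursor, extends it greedily, and repeats.  Returns
    (list of lists of lick indices, sorted non-bout indices).
    """
    onsets = list(onsets)
    n = len(onsets)

    def initiates(i):
        if i + init_n > n:
            return False
        window = onsets[i : i + init_n]
        return all(
            (b - a) <= init_ili_max for a, b in zip(window, window[1:])
        )

    bouts = []
    cursor = 0
    while cursor < n:
        candidates = [i for i in range(cursor, n) if initiates(i)]
        if not candidates:
            break
        start = candidates[0]
        members = list(range(start, start + init_n))
        j = start + init_n - 1
        while j + 1 < n and (onsets[j + 1] - onsets[j]) <= term_gap:
            members.append(j + 1)
            j += 1
        bouts.append(members)
        cursor = j + 1
    in_bout = {i for bout in bouts for i in bout}
    nonbout = sorted(set(range(n)) - in_bout)
    return bouts, nonbout


def brute_force_ks(a, b):
    """Reference two-sample KS statistic: double loop over pooled points."""
    a, b = list(a), list(b)
    best = 0.0
    for x in a + b:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best
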