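"""Independent brute-force reference for the repeat scanner.

Same search semantics as ``dgrscan.scan.scan_residues`` but a deliberately
different mechanism: instead of decomposing each alignment offset into maximal
clean runs (and special-casing tandem overlaps), the oracle enumerates every
seed window directly via cumulative sums of the column-match indicator and
extends each seed individually.  Agreement between the two therefore
cross-checks the run-decomposition shortcuts of the production scanner.
"""

from __future__ import annotations

import numpy as np


def _col_ok(t: str, v: str, wc: str) -> bool:
    if t == "N" or v == "N":
        return False
    return t == wc or t == v


def oracle_extend(res: str, t: int, v: int, ln: int, wc: str):
    """Reference maximal extension: alternate one left step, one right step."""
    L = len(res)
    gap = abs(v - t)
    while True:
        grew = False
        if min(t, v) > 0 and ln < gap and _col_ok(res[t - 1], res[v - 1], wc):
            t -= 1
            v -= 1
            ln += 1
            grew = True
        if max(t, v) + ln < L and ln < gap and _col_ok(res[t + ln], res[v + ln], wc):
            ln += 1
            grew = True
        if not grew:
            return t, v, ln


def oracle_scan(
    res: str,
    window: int = 50,
    wildcard: str = "A",
    min_wildcard: int = 10,
    min_substitutions: int = 7,
    step: int = 1,
):
    """All maximal TR/VR pairs passing the filters, as (ts, te, vs, ve)."""
    L = len(res)
    W = window
    if L < 2 * W:
        return []
    arr = np.frombuffer(res.encode(), dtype=np.uint8)
    wc_code, n_code = ord(wildcard), ord("N")

    pairs = set()
    for d in range(W, L - W + 1):
        x, y = arr[: L - d], arr[d:]
        not_n = (x != n_code) & (y != n_code)
        for tr_is_left in (True, False):
            t_side = x if tr_is_left else y
            ok = ((t_side == wc_code) | (x == y)) & not_n
            csum = np.concatenate(([0], np.cumsum(ok)))
            seed = np.flatnonzero(csum[W:] - csum[:-W] == W)
            for i in seed.tolist():
                ta, va = (i, i + d) if tr_is_left else (i + d, i)
                if ta % step != 0:
                    continue
                ts, vs, ln = oracle_extend(res, ta, va, W, wildcard)
                pairs.add((ts, ts + ln, vs, vs + ln))

    plist = sorted(pairs)
    kept = []
    for p in plist:
        if any(
            q != p
            and q[2] - q[0] == p[2] - p[0]
            and q[0] <= p[0] <= p[1] <= q[1]
            and q[2] <= p[2] <= p[3] <= q[3]
            for q in plist
        ):
            continue
        tr_seq = res[p[0] : p[1]]
        vr_seq = res[p[2] : p[3]]
        n_sub = sum(1 for a, b in zip(tr_seq, vr_seq) if a == wildcard and b != a)
        if tr_seq.count(wildcard) >= min_wildcard and n_sub >= min_substitutions:
            kept.append(p)
    return kept


def hits_as_tuples(hits):
    """Scanner hits in the oracle's tuple form, sorted."""
    return sorted((*h.tr_interval, *h.vr_interval) for h in hits)
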