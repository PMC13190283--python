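"""Deterministic base-pair-maximization folding (Nussinov-style).

Not a thermodynamic folder: the objective is the number of nested base
pairs, subject to a minimum helix length of 3 stacked pairs and a minimum
hairpin loop of 3 nt, with the G.T wobble permitted by default. The
helix-length constraint is what keeps pure pair maximization from pairing
everything in sight.

Two refinements matter for structure annotation:

* ``locality=True`` breaks the (very common) ties between equal-count
  structures toward short-range pairing, by charging each pair a penalty
  equal to its span against a large per-pair reward. Chance long-range
  complementarity otherwise routinely repartners designed stems across
  domains.
* ``filter_helices`` drops long-range helices too short to be credible,
  the post-hoc counterpart of the same problem.

The dynamic program is vectorized over interval length: ``B[s, i]`` holds
the optimum for the interval ``[i, i+s]``. A banded variant (``max_span``)
scores every interval up to a span bound in one pass, which is how all
candidate domain-V windows are scored at once.
"""

from __future__ import annotations

import numpy as np

from .core_io import pairs_ok

MIN_LOOP = 3  # minimum unpaired nucleotides closed by a pair
MIN_HELIX = 3  # minimum consecutive stacked pairs per helix
_W = 2048  # per-pair reward in locality mode; dwarfs any span penalty sum


def _can_pair_matrix(seq: str, wobble: bool) -> np.ndarray:
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros((256, 256), dtype=bool)
    for a in "ACGT":
        for b in "ACGT":
            if pairs_ok(a, b, wobble):
                lut[ord(a), ord(b)] = True
    return lut[np.ix_(idx, idx)]


def _helix_value(h: int, s: int, locality: bool) -> int:
    """DP value of h stacked pairs closing an interval of span s."""
    if not locality:
        return h
    return _W * h - (h * s - h * (h - 1))


def pair_tables(seq: str, wobble: bool = True, max_span: int | None = None,
                locality: bool = False):
    """DP tables ``(B, H)``: ``B[s, i]`` = optimal value on ``[i, i+s]``;
    ``H[s, i]`` = stackable helix length for the closing pair ``(i, i+s)``.

    Without ``locality`` the value is the pair count. With ``max_span``,
    only intervals of span <= max_span are computed (exact for those,
    since sub-problems of a bounded interval are bounded).
    """
    n = len(seq)
    smax = n - 1 if max_span is None else min(max_span, n - 1)
    can = _can_pair_matrix(seq, wobble)
    dtype = np.int32 if locality else np.int16
    B = np.zeros((smax + 1, n), dtype=dtype)
    H = np.zeros((smax + 1, n), dtype=np.int16)
    for s in range(1, smax + 1):
        m = n - s  # number of intervals of this span
        # helix stack length for closing pair (i, i+s)
        if s - 1 >= MIN_LOOP:
            cp = can[np.arange(m), np.arange(s, n)]
            inner = H[s - 2, 1 : m + 1] if s >= 2 else np.zeros(m, dtype=np.int16)
            H[s, :m] = np.where(cp, 1 + inner, 0)
        best = np.zeros(m, dtype=dtype)
        # splits [i..i+t] + [i+t+1..i+s] (t = s-1 covers "last nt unpaired")
        for t in range(s):
            cand = B[t, :m] + B[s - 1 - t, t + 1 : t + 1 + m]
            np.maximum(best, cand, out=best)
        # helix of h stacked pairs starting exactly at (i, i+s)
        hmax = int(H[s, :m].max(initial=0))
        for h in range(MIN_HELIX, hmax + 1):
            ok = H[s, :m] >= h
            inner_s = s - 2 * h
            inner = B[inner_s, h : h + m] if inner_s >= 1 else np.zeros(m, dtype=dtype)
            cand = np.where(ok, _helix_value(h, s, locality) + inner, 0).astype(dtype)
            np.maximum(best, cand, out=best)
        B[s, :m] = best
    return B, H


def _traceback(B, H, i: int, j: int, pairs: list, locality: bool):
    """Recover one optimal structure for [i, j].

    Deterministic option order: split decompositions are preferred over an
    enclosing helix when both reach the optimum — ties are common under
    pure maximization and separate subtrees are the structurally
    conservative reading.
    """
    stack = [(i, j)]
    while stack:
        i, j = stack.pop()
        if j <= i:
            continue
        s = j - i
        target = int(B[s, i])
        if target == 0:
            continue
        done = False
        for t in range(s):
            if int(B[t, i]) + int(B[s - 1 - t, i + t + 1]) == target:
                stack.append((i, i + t))
                stack.append((i + t + 1, j))
                done = True
                break
        if done:
            continue
        hmax = int(H[s, i])
        for h in range(hmax, MIN_HELIX - 1, -1):
            inner_s = s - 2 * h
            inner = int(B[inner_s, i + h]) if inner_s >= 1 else 0
            if _helix_value(h, s, locality) + inner == target:
                for t in range(h):
                    pairs.append((i + t, j - t))
                if inner_s >= 1:
                    stack.append((i + h, j - h))
                break


def max_pairs(seq: str, wobble: bool = True,
              locality: bool = False) -> tuple[int, list[tuple[int, int]]]:
    """Optimal nested pairing of *seq*; returns ``(n_pairs, pairs)`` with
    0-based ``(i, j)`` pairs sorted by ``i``."""
    n = len(seq)
    if n < 2 * MIN_HELIX + MIN_LOOP:
        return 0, []
    B, H = pair_tables(seq, wobble, locality=locality)
    pairs: list[tuple[int, int]] = []
    _traceback(B, H, 0, n - 1, pairs, locality)
    pairs.sort()
    return len(pairs), pairs


def paired_mask(n: int, pairs: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for i, j in pairs:
        mask[i] = mask[j] = True
    return mask


def unpaired_runs(n: int, pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximal unpaired stretches as 0-based half-open ``(start, stop)``."""
    mask = paired_mask(n, pairs)
    runs, i = [], 0
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def top_level_subtrees(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Outermost closed stem-loop intervals (0-based inclusive), left to right."""
    subtrees, end = [], -1
    for i, j in sorted(pairs):
        if i > end:
            subtrees.append((i, j))
            end = j
    return subtrees


def helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into stacked helices."""
    out: list[list[tuple[int, int]]] = []
    for p in sorted(pairs):
        if out and p[0] == out[-1][-1][0] + 1 and p[1] == out[-1][-1][1] - 1:
            out[-1].append(p)
        else:
            out.append([p])
    return out


def filter_helices(
    pairs: list[tuple[int, int]],
    min_len: int = 5,
    max_span: int = 60,
) -> list[tuple[int, int]]:
    """Drop low-confidence long-range helices.

    Real inter-domain architecture is either compact (span <= *max_span*)
    or supported by a long stem (>= *min_len* stacked pairs, e.g. the
    closing stem of an ORF-hosting domain); chance 3-4 bp complementarity
    between distant unpaired stretches is neither.
    """
    kept: list[tuple[int, int]] = []
    for hx in helices(pairs):
        span = hx[0][1] - hx[0][0]
        if len(hx) >= min_len or span <= max_span:
            kept.extend(hx)
    return sorted(kept)


def long_stems(
    seq: str,
    min_len: int = 10,
    min_span: int = 60,
) -> list[tuple[int, int, int]]:
    """Long-range anchor stems: maximal exact Watson-Crick stacks
    ``(i, j, h)`` pairing ``seq[i+t]`` with ``seq[j-t]`` for ``t < h``,
    with ``h >= min_len`` and span ``j - i > min_span``.

    At these lengths chance complementarity is negligible, so such stems
    are treated as the closing helices of large (ORF-hosting) domains.
    Returned greedily longest-first, mutually nested-or-disjoint.
    """
    n = len(seq)
    if n < 2 * min_len + MIN_LOOP:
        return []
    can = _can_pair_matrix(seq, wobble=False)
    run = np.zeros((n, n), dtype=np.int16)
    cands = []
    # run[i, j] = stacked pair count starting at (i, j) going inward
    for s in range(MIN_LOOP + 1, n):
        i_idx = np.arange(0, n - s)
        j_idx = i_idx + s
        inner = run[i_idx + 1, j_idx - 1]
        run[i_idx, j_idx] = np.where(can[i_idx, j_idx], 1 + inner, 0)
    ii, jj = np.nonzero(run >= min_len)
    for i, j in zip(ii, jj):
        if j - i <= min_span:
            continue
        if i > 0 and j < n - 1 and can[i - 1, j + 1]:
            continue  # not outermost
        cands.append((int(i), int(j), int(run[i, j])))
    cands.sort(key=lambda c: (-c[2], c[0]))
    chosen: list[tuple[int, int, int]] = []

    def compatible(a, b) -> bool:
        (i1, j1, h1), (i2, j2, h2) = a, b
        nested = (i1 + h1 <= i2 and j2 <= j1 - h1) or (i2 + h2 <= i1 and j1 <= j2 - h2)
        disjoint = j1 < i2 or j2 < i1
        return nested or disjoint

    for c in cands:
        if all(compatible(c, x) for x in chosen):
            chosen.append(c)
    chosen.sort()
    return chosen


def dot_bracket(n: int, pairs: list[tuple[int, int]]) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)
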