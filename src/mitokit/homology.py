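"""Pairwise local homology search by exact-seed chaining and extension.

The engine behind genome self-comparison (repeat detection), mt-vs-cp
scanning (plastid-derived segments) and masked shared-sequence totals:

1. exact k-mer seed matches between query and subject (both strands),
2. seeds chained per diagonal (with a small band to tolerate indels),
3. ungapped X-drop extension of each chain on both ends,
4. verification by global alignment (edlib) of the extended segments,
   reporting percent identity over alignment columns.

For very short, highly diverged targets an exact seed of useful length may
not exist; :func:`sweep_search` complements the seed pass with a sliding
subject-window infix alignment (edlib HW mode), which detects every
substitution-only match above the identity floor at the cost of a dense
scan. Callers that need guaranteed recovery of segments near the minimum
length combine both passes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .model import revcomp

__all__ = ["Hit", "search", "sweep_search", "alignment_identity"]

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class Hit:
    """A local alignment between query and subject, 1-based inclusive.

    Query coordinates are always on the forward strand. ``strand`` is the
    subject orientation: for ``-`` the aligned subject sequence is the
    reverse complement of ``subject[s_start-1:s_end]``.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float  # percent over alignment columns
    aln_len: int  # alignment columns including indels

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start + 1


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int):
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        seg = arr[j : n + j].astype(np.int64)
        codes = codes * 4 + np.where(seg > 3, 0, seg)
        valid &= seg <= 3
    return codes, valid


def _seed_pairs(qarr, sarr, k: int, max_occ: int):
    """All (query_pos, subject_pos) pairs of identical k-mers, 0-based."""
    qcodes, qvalid = _kmer_codes(qarr, k)
    scodes, svalid = _kmer_codes(sarr, k)
    spos = np.flatnonzero(svalid)
    if spos.size == 0 or not qvalid.any():
        return np.empty(0, np.int64), np.empty(0, np.int64)
    svals = scodes[spos]
    order = np.argsort(svals, kind="stable")
    sorted_vals = svals[order]
    sorted_pos = spos[order]
    qpos = np.flatnonzero(qvalid)
    qvals = qcodes[qpos]
    left = np.searchsorted(sorted_vals, qvals, "left")
    right = np.searchsorted(sorted_vals, qvals, "right")
    cnt = right - left
    if max_occ:
        cnt = np.where(cnt > max_occ, 0, cnt)
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    qi = np.repeat(qpos, cnt)
    starts = np.repeat(left, cnt)
    offsets = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    si = sorted_pos[starts + offsets]
    return qi.astype(np.int64), si

def _diag_chains(qi, si, k: int, max_gap: int):
    """Chain seeds sharing a diagonal with query gaps <= max_gap.

    Returns arrays (q0, q1, s0, s1, nseeds), 0-based inclusive endpoints.
    """
    if qi.size == 0:
        return [np.empty(0, np.int64)] * 5
    diag = si - qi
    order = np.lexsort((qi, diag))
    qi, si, diag = qi[order], si[order], diag[order]
    brk = np.flatnonzero((np.diff(diag) != 0) | (np.diff(qi) > max_gap + k))
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk, [qi.size - 1]))
    return (
        qi[starts],
        qi[ends] + k - 1,
        si[starts],
        si[ends] + k - 1,
        ends - starts + 1,
    )


def _merge_banded(q0, q1, s0, s1, ns, band: int, max_gap: int):
    """Union-find merge of chains on nearby diagonals (indel tolerance)."""
    n = q0.size
    if n <= 1 or band <= 0:
        return q0, q1, s0, s1, ns
    diag = s0 - q0
    order = np.argsort(diag, kind="stable")
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    od = diag[order]
    for ii in range(n):
        a = order[ii]
        jj = ii + 1
        while jj < n and od[jj] - od[ii] <= band:
            b = order[jj]
            if min(q1[a], q1[b]) + max_gap >= max(q0[a], q0[b]) and min(
                s1[a], s1[b]
            ) + max_gap >= max(s0[a], s0[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
            jj += 1
    roots = np.array([find(a) for a in range(n)])
    out = {}
    for a in range(n):
        r = roots[a]
        if r not in out:
            out[r] = [q0[a], q1[a], s0[a], s1[a], ns[a]]
        else:
            o = out[r]
            o[0] = min(o[0], q0[a])
            o[1] = max(o[1], q1[a])
            o[2] = min(o[2], s0[a])
            o[3] = max(o[3], s1[a])
            o[4] += ns[a]
    arr = np.array(list(out.values()), dtype=np.int64).T
    return arr[0], arr[1], arr[2], arr[3], arr[4]


def _xdrop_extend(qarr, sarr, q0, q1, s0, s1, match=2, mismatch=-3, xdrop=40):
    """Ungapped extension of both ends along the chain diagonal."""
    # left
    score = best = 0
    bq, bs = q0, s0
    i, j = q0 - 1, s0 - 1
    while i >= 0 and j >= 0:
        score += match if qarr[i] == sarr[j] and qarr[i] <= 3 else mismatch
        if score > best:
            best, bq, bs = score, i, j
        if best - score > xdrop:
            break
        i -= 1
        j -= 1
    q0, s0 = bq, bs
    # right
    score = best = 0
    bq, bs = q1, s1
    i, j = q1 + 1, s1 + 1
    nq, nsub = qarr.size, sarr.size
    while i < nq and j < nsub:
        score += match if qarr[i] == sarr[j] and qarr[i] <= 3 else mismatch
        if score > best:
            best, bq, bs = score, i, j
        if best - score > xdrop:
            break
        i += 1
        j += 1
    return q0, bq, s0, bs


def alignment_identity(a: str, b: str):
    """(percent identity, alignment columns) of a global edlib alignment."""
    res = edlib.align(a, b, task="path")
    dist = res["editDistance"]
    cigar = res["cigar"] or ""
    cols = sum(int(n) for n, _ in _CIG_RE.findall(cigar))
    if cols == 0:
        return 0.0, 0
    return 100.0 * (cols - dist) / cols, cols


def trimmed_local_alignment(a: str, b: str, match=1, mismatch=-2, gap=-3):
    """Best-scoring local window along the global edlib alignment path.

    Returns ``(a0, a1, b0, b1, identity_percent, columns)`` with 0-based
    inclusive coordinates of the trimmed window in each sequence, or None if
    the sequences share nothing scoring positive. Trimming a maximal-score
    window places boundaries at the last positions that still pay for
    themselves, which keeps reported segment edges tight even when the
    candidate region was extended generously.
    """
    res = edlib.align(a, b, task="path")
    cigar = res["cigar"] or ""
    score = best = 0
    ai = bi = 0
    w_a = w_b = 0  # window start when score was reset
    best_win = None
    for n_s, op in _CIG_RE.findall(cigar):
        n = int(n_s)
        for _ in range(n):
            if op == "=":
                delta = match
            elif op == "X":
                delta = mismatch
            else:
                delta = gap
            if score <= 0:
                score = 0
                w_a, w_b = ai, bi
            score += delta
            if op in ("=", "X"):
                ai += 1
                bi += 1
            elif op == "I":  # insertion in a w.r.t. b
                ai += 1
            else:
                bi += 1
            if score > best:
                best = score
                best_win = (w_a, ai - 1, w_b, bi - 1)
    if best_win is None:
        return None
    a0, a1, b0, b1 = best_win
    ident, cols = alignment_identity(a[a0 : a1 + 1], b[b0 : b1 + 1])
    return a0, a1, b0, b1, ident, cols


def _alignment_columns(a: str, b: str):
    """Global alignment as per-column tuples (op, a_pos, b_pos), 0-based."""
    res = edlib.align(a, b, task="path")
    cols = []
    ai = bi = 0
    for n_s, op in _CIG_RE.findall(res["cigar"] or ""):
        for _ in range(int(n_s)):
            cols.append((op, ai, bi))
            if op in ("=", "X"):
                ai += 1
                bi += 1
            elif op == "I":
                ai += 1
            else:
                bi += 1
    return cols


def _feasible_window(cols, min_len: int, min_identity: float):
    """Longest alignment window of >= min_len columns at >= the identity
    floor, or None. Two-pointer over transformed column scores: a window is
    feasible iff sum of (match - floor) over it is non-negative."""
    floor = min_identity / 100.0
    n = len(cols)
    if n < min_len:
        return None
    prefix = [0.0]
    for op, _, _ in cols:
        prefix.append(prefix[-1] + ((1.0 - floor) if op == "=" else -floor))
    best = None
    run_min, run_arg = prefix[0], 0
    for e in range(min_len, n + 1):
        s_lim = e - min_len
        if prefix[s_lim] < run_min:
            run_min, run_arg = prefix[s_lim], s_lim
        if prefix[e] >= run_min - 1e-9:
            if best is None or (e - run_arg) > (best[1] - best[0]):
                best = (run_arg, e)
    if best is None:
        return None
    s, e = best
    # shrink to match columns at both edges
    while s < e and cols[s][0] != "=":
        s += 1
    while e > s and cols[e - 1][0] != "=":
        e -= 1
    return s, e


def _verify_candidates(query, subject, cands, min_len, min_identity):
    out = []
    seen = set()
    for q0, q1, s0, s1 in cands:
        if q1 - q0 + 1 < min_len or s1 - s0 + 1 < min_len:
            continue
        key = (q0, q1, s0, s1)
        if key in seen:
            continue
        seen.add(key)
        a, b = query[q0 : q1 + 1], subject[s0 : s1 + 1]
        trimmed = trimmed_local_alignment(a, b)
        if trimmed is not None:
            a0, a1, b0, b1, ident, colsn = trimmed
            if colsn >= min_len and ident >= min_identity:
                out.append((q0 + a0, q0 + a1, s0 + b0, s0 + b1, ident, colsn))
                continue
        # the max-score window can fall short of min_len when mutations
        # cluster, and X-drop extension may have clipped a diverged end;
        # re-examine a padded slice for any >=min_len window meeting the
        # identity floor
        pad_l = min(min_len, q0, s0)
        pad_r = min(min_len, len(query) - 1 - q1, len(subject) - 1 - s1)
        pq0, pq1 = q0 - pad_l, q1 + pad_r
        ps0, ps1 = s0 - pad_l, s1 + pad_r
        a2, b2 = query[pq0 : pq1 + 1], subject[ps0 : ps1 + 1]
        if q1 - q0 == s1 - s0:
            # an ungapped candidate: judge the diagonal itself, immune to
            # flank-induced path wander in a global alignment
            cols = [
                ("=" if x == y else "X", i, i)
                for i, (x, y) in enumerate(zip(a2, b2))
            ]
        else:
            cols = _alignment_columns(a2, b2)
        win = _feasible_window(cols, min_len, min_identity)
        if win is None:
            continue
        s_i, e_i = win
        qa = [c[1] for c in cols[s_i:e_i]]
        sb = [c[2] for c in cols[s_i:e_i]]
        ident, colsn = alignment_identity(
            a2[qa[0] : qa[-1] + 1], b2[sb[0] : sb[-1] + 1]
        )
        out.append(
            (pq0 + qa[0], pq0 + qa[-1], ps0 + sb[0], ps0 + sb[-1], ident, colsn)
        )
    return out


def search(
    query: str,
    subject: str,
    *,
    k: int = 11,
    min_len: int = 30,
    min_identity: float = 80.0,
    strand: str = "both",
    max_gap: int = 60,
    band: int = 12,
    min_seeds: int = 1,
    max_occ: int = 64,
    xdrop: int = 40,
    self_mode: bool = False,
) -> list:
    """Seed-chain-extend local search of ``query`` against ``subject``.

    ``self_mode`` (query is subject) reports each forward pair once
    (subject position strictly greater than query position) and drops the
    trivial self-diagonal.
    """
    if k < 1 or k > 25:
        raise ValueError("seed size k must be in [1, 25]")
    if min_len < k:
        raise ValueError(f"min_len ({min_len}) must be >= seed size k ({k})")
    qarr = _encode(query)
    hits = []
    for st in ("+", "-") if strand == "both" else (strand,):
        subj = subject if st == "+" else revcomp(subject)
        sarr = _encode(subj)
        qi, si = _seed_pairs(qarr, sarr, k, max_occ)
        if self_mode and st == "+":
            keep = si > qi
            qi, si = qi[keep], si[keep]
        q0, q1, s0, s1, ns = _diag_chains(qi, si, k, max_gap)
        # drop weak chains before the (python-level) banded merge; min_seeds
        # is judged per diagonal chain
        keep = (ns >= min_seeds) | (q1 - q0 + 1 >= min_len)
        q0, q1, s0, s1, ns = q0[keep], q1[keep], s0[keep], s1[keep], ns[keep]
        q0, q1, s0, s1, ns = _merge_banded(q0, q1, s0, s1, ns, band, max_gap)
        cands = []
        for a in range(len(np.atleast_1d(q0))):
            e = _xdrop_extend(qarr, sarr, int(q0[a]), int(q1[a]), int(s0[a]), int(s1[a]), xdrop=xdrop)
            cands.append(e)
        for q0_, q1_, s0_, s1_, ident, cols in _verify_candidates(
            query, subj, cands, min_len, min_identity
        ):
            if st == "+":
                hits.append(
                    Hit(q0_ + 1, q1_ + 1, s0_ + 1, s1_ + 1, "+", ident, cols)
                )
            else:
                L = len(subject)
                hits.append(
                    Hit(
                        q0_ + 1,
                        q1_ + 1,
                        L - 1 - s1_ + 1,
                        L - 1 - s0_ + 1,
                        "-",
                        ident,
                        cols,
                    )
                )
    return hits


def sweep_search(
    query: str,
    subject: str,
    *,
    window: int = 24,
    step: int = 7,
    max_mismatch: int = 8,
    min_len: int = 30,
    min_identity: float = 80.0,
    strand: str = "both",
    xdrop: int = 40,
) -> list:
    """Exhaustive sliding-window mismatch sweep of subject against query.

    For every step-aligned subject window of ``window`` bp, the Hamming
    distance to the query at every offset is computed by vectorised
    correlation; offsets with at most ``max_mismatch`` mismatches become
    candidates, X-drop extended and verified like seed chains. A covering
    argument over step-aligned windows shows that any substitution-only
    match of length >= 30 bp at >= 80% identity always yields at least one
    window within 8 mismatches at the defaults, so this pass cannot miss
    such a segment — unlike an exact-seed pass, whose shortest seed may not
    survive the divergence. Cost is O(|query| * |subject| * window / step);
    meant for organelle-scale inputs, not chromosome-scale data.
    """
    qarr = _encode(query)
    nq = qarr.size
    hits = []
    hit_score = window - max_mismatch
    batch = 512
    for st in ("+", "-") if strand == "both" else (strand,):
        subj = subject if st == "+" else revcomp(subject)
        sarr = _encode(subj)
        ns = sarr.size
        if nq < window or ns < window:
            continue
        raw = []  # (diagonal, q0, s0) of above-threshold windows
        # match count of subject window [a, a+window) vs query at a + d, for
        # every step-aligned a and every diagonal d; diagonals batched over
        # a sentinel-padded query (sentinels never match), window sums via
        # wrapping uint8 cumulative sums (exact for sums < 256)
        off = ns - window  # most negative diagonal
        qpad = np.full(off + nq + batch + ns, 64, dtype=np.uint8)
        qpad[off : off + nq] = qarr
        a_sub = np.arange(0, ns - window + 1, step)
        for d0 in range(-off, nq - window + 1, batch):
            start = off + d0
            view = np.lib.stride_tricks.sliding_window_view(
                qpad[start : start + batch - 1 + ns], ns
            )[:batch]
            eq = view == sarr[None, :]  # (batch diagonals, ns positions)
            csum = np.zeros((eq.shape[0], ns + 1), dtype=np.uint8)
            np.add.accumulate(eq.view(np.uint8), axis=1, out=csum[:, 1:])
            wsum = csum[:, a_sub + window] - csum[:, a_sub]  # mod 256, exact
            rows, cols_ = np.nonzero(wsum >= hit_score)
            for dd, ri in zip(rows.tolist(), cols_.tolist()):
                a = int(a_sub[ri])
                q0 = a + d0 + dd
                if 0 <= q0 <= nq - window:
                    raw.append((q0 - a, q0, a))
        # windows of one long match share a diagonal: merge runs, extend once
        raw.sort()
        cands = []
        i = 0
        while i < len(raw):
            d, q0, s0 = raw[i]
            q1 = q0
            j = i + 1
            while j < len(raw) and raw[j][0] == d and raw[j][1] - q1 <= window:
                q1 = raw[j][1]
                j += 1
            cands.append(
                _xdrop_extend(
                    qarr,
                    sarr,
                    q0,
                    q1 + window - 1,
                    s0,
                    q1 - d + window - 1,
                    xdrop=xdrop,
                )
            )
            i = j
        for q0_, q1_, s0_, s1_, ident, cols in _verify_candidates(
            query, subj, cands, min_len, min_identity
        ):
            if st == "+":
                hits.append(Hit(q0_ + 1, q1_ + 1, s0_ + 1, s1_ + 1, "+", ident, cols))
            else:
                L = len(subject)
                hits.append(
                    Hit(q0_ + 1, q1_ + 1, L - s1_, L - s0_, "-", ident, cols)
                )
    return hits
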