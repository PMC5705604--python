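"""Sequence encoding, pairwise alignment and k-mer anchor utilities.

Sequences are handled internally as ``numpy.uint8`` arrays with the 2-bit
code A=0, C=1, G=2, T=3; any other letter (N and IUPAC ambiguity codes)
maps to 4 and never counts as a match.

Three alignment layers live here:

- a global Needleman-Wunsch aligner (match +1, mismatch -1, gap -1) with a
  deterministic traceback that also reports the number of matched bases --
  the primitive behind the monomer similarity statistic;
- greedy local-hit search built on :class:`Bio.Align.PairwiseAligner`, used
  for representative-monomer scoring and satellite masking;
- unique k-mer anchor matching between long sequences, used by the
  structural-variant pipeline to find colinear blocks and to project
  intervals from one genome onto another.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on every import
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq) -> np.ndarray:
    """Encode a DNA string (or bytes) as a uint8 code array."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(bytes(seq), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case DNA string."""
    return _DECODE[np.asarray(arr, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence."""
    return _COMP[np.asarray(arr, dtype=np.uint8)][::-1]


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nw_core(a, b):  # pragma: no cover - compiled
    n = a.shape[0]
    m = b.shape[0]
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    ptr = np.empty((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    score[0, 0] = 0
    for i in range(1, n + 1):
        score[i, 0] = -i
        ptr[i, 0] = 1
    for j in range(1, m + 1):
        score[0, j] = -j
        ptr[0, j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = 1 if (ai == b[j - 1] and ai < 4) else -1
            d = score[i - 1, j - 1] + sub
            u = score[i - 1, j] - 1
            left = score[i, j - 1] - 1
            # tie-break preference: diagonal, then up, then left
            if d >= u and d >= left:
                score[i, j] = d
                ptr[i, j] = 0
            elif u >= left:
                score[i, j] = u
                ptr[i, j] = 1
            else:
                score[i, j] = left
                ptr[i, j] = 2
    i = n
    j = m
    matches = 0
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return score[n, m], matches


def global_alignment(a, b) -> tuple[int, int]:
    """Globally align two sequences and return ``(score, matched_bases)``.

    Scoring is match +1, mismatch -1, gap -1 with no end-gap forgiveness.
    Matched bases are counted on one optimal traceback with the fixed
    tie-break order diagonal > up > left, so the result is deterministic.
    """
    ea, eb = encode(a), encode(b)
    if ea.size == 0 or eb.size == 0:
        raise ValueError("cannot align an empty sequence")
    s, m = _nw_core(ea, eb)
    return int(s), int(m)


# ---------------------------------------------------------------------------
# Local hits (Biopython-backed)
# ---------------------------------------------------------------------------

def _make_local_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # affine gaps: keeps spurious gapped extensions through random sequence
    # clearly below the score of genuine homology
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


_local_aligner = None


def _count_identities(alignment) -> tuple[int, int, int]:
    """(matches, query columns, total columns incl. gaps) of an alignment."""
    t_blocks, q_blocks = alignment.aligned
    matches = 0
    qcols = 0
    tseq = alignment.target
    qseq = alignment.query
    prev_t = prev_q = None
    gaps = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            gaps += (ts - prev_t) + (qs - prev_q)
        sub_t = np.frombuffer(str(tseq[ts:te]).encode(), dtype=np.uint8)
        sub_q = np.frombuffer(str(qseq[qs:qe]).encode(), dtype=np.uint8)
        matches += int(np.sum(sub_t == sub_q))
        qcols += qe - qs
        prev_t, prev_q = te, qe
    return matches, qcols, qcols + gaps


def local_hits(query, region, identity_floor: float = 0.7,
               min_length: int = 30, max_hits: int = 10_000) -> list[dict]:
    """Greedy non-overlapping local hits of ``query`` inside ``region``.

    The best local alignment is taken, its footprint masked with N, and the
    search repeated until the next hit falls below ``identity_floor`` or
    ``min_length`` aligned query columns.  Each hit is reported as a dict
    with keys ``start``, ``end`` (0-based half-open on the region),
    ``identity`` and ``length`` (aligned columns) and ``score``.
    """
    global _local_aligner
    if _local_aligner is None:
        _local_aligner = _make_local_aligner()
    qs = decode(encode(query)) if not isinstance(query, str) else query
    rs = list(decode(encode(region)) if not isinstance(region, str) else region)
    hits: list[dict] = []
    for _ in range(max_hits):
        target = "".join(rs)
        try:
            alns = _local_aligner.align(target, qs)
            aln = alns[0]
        except (IndexError, ValueError):
            break
        if aln.score <= 0:
            break
        matches, cols, total_cols = _count_identities(aln)
        if cols == 0:
            break
        identity = matches / total_cols
        t_blocks = aln.aligned[0]
        start = int(t_blocks[0][0])
        end = int(t_blocks[-1][1])
        if cols < min_length or identity < identity_floor:
            break
        hits.append({"start": start, "end": end, "identity": identity,
                     "length": cols, "score": float(aln.score)})
        for i in range(start, end):
            rs[i] = "N"
    return hits


# ---------------------------------------------------------------------------
# Unique k-mer anchors between long sequences
# ---------------------------------------------------------------------------

def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers plus a validity mask (no non-ACGT base).

    Returns ``(codes, valid)`` with one entry per k-mer start position.
    """
    a = np.asarray(arr, dtype=np.uint8)
    n = a.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    bad = (a >= 4)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        codes = (codes << 2) | (a[j:j + n] & 3)
        invalid |= bad[j:j + n]
    return codes, ~invalid


def _unique_positions(codes: np.ndarray, valid: np.ndarray):
    codes = codes[valid]
    pos = np.nonzero(valid)[0]
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    sp = pos[order]
    first = np.ones(sc.size, dtype=bool)
    first[1:] = sc[1:] != sc[:-1]
    starts = np.nonzero(first)[0]
    counts = np.diff(np.append(starts, sc.size))
    uniq = counts == 1
    return sc[starts][uniq], sp[starts][uniq]


def anchors(query: np.ndarray, target: np.ndarray, k: int = 21):
    """Match k-mers unique in both sequences, forward and reverse strand.

    Returns ``(qpos, tpos, strand)`` arrays sorted by query position;
    ``strand`` is +1 / -1.  For a reverse-strand anchor ``tpos`` is the
    start of the matching k-mer on the forward target strand.
    """
    qc, qv = kmer_codes(query, k)
    q_codes, q_pos = _unique_positions(qc, qv)

    tc, tv = kmer_codes(target, k)
    rc_t = revcomp(target)
    tcr, tvr = kmer_codes(rc_t, k)
    # uniqueness must hold across both strands of the target
    all_codes = np.concatenate([tc[tv], tcr[tvr]])
    all_pos = np.concatenate([np.nonzero(tv)[0], -1 - np.nonzero(tvr)[0]])
    order = np.argsort(all_codes, kind="stable")
    sc = all_codes[order]
    sp = all_pos[order]
    first = np.ones(sc.size, dtype=bool)
    first[1:] = sc[1:] != sc[:-1]
    idx = np.nonzero(first)[0]
    counts = np.diff(np.append(idx, sc.size))
    uniq = counts == 1
    t_codes = sc[idx][uniq]
    t_pos = sp[idx][uniq]

    inter, qi, ti = np.intersect1d(q_codes, t_codes, assume_unique=True,
                                   return_indices=True)
    qp = q_pos[qi]
    tp_raw = t_pos[ti]
    strand = np.where(tp_raw >= 0, 1, -1).astype(np.int8)
    n_t = target.shape[0]
    # position on forward strand of the k-mer start
    tp = np.where(tp_raw >= 0, tp_raw, n_t - k - (-1 - tp_raw))
    order = np.argsort(qp, kind="stable")
    return qp[order], tp[order], strand[order]


def project_interval(query: np.ndarray, target: np.ndarray,
                     start: int, end: int, k: int = 21,
                     min_anchors: int = 3):
    """Project a query interval [start, end) onto the target via anchors.

    The interval sequence is matched to the target with unique k-mer
    anchors; the modal diagonal (within a small band) defines an affine
    placement.  Returns ``(t_start, t_end, strand, n_anchors)`` or ``None``
    when fewer than ``min_anchors`` consistent anchors are found.
    """
    seg = np.asarray(query[start:end], dtype=np.uint8)
    if seg.size < k:
        return None
    qp, tp, strand = anchors(seg, target, k=k)
    if qp.size < min_anchors:
        return None
    best = None
    for s in (1, -1):
        sel = strand == s
        if int(sel.sum()) < min_anchors:
            continue
        if s == 1:
            diag = tp[sel] - qp[sel]
        else:
            diag = tp[sel] + qp[sel]
        med = np.median(diag)
        ok = np.abs(diag - med) <= 100
        n_ok = int(ok.sum())
        if n_ok >= min_anchors and (best is None or n_ok > best[0]):
            best = (n_ok, s, qp[sel][ok], tp[sel][ok])
    if best is None:
        return None
    n_ok, s, qpo, tpo = best
    if s == 1:
        t_start = int(tpo.min() - qpo[np.argmin(tpo)])
        t_end = int(tpo.max() + (seg.size - qpo[np.argmax(tpo)]))
    else:
        # reverse strand: query start maps near target end
        t_start = int(tpo.min() - (seg.size - k - qpo[np.argmin(tpo)]))
        t_end = int(tpo.max() + k + qpo[np.argmax(tpo)])
    t_start = max(0, t_start)
    t_end = min(int(target.shape[0]), t_end)
    return t_start, t_end, s, n_ok
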