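"""Structural variants from whole-genome comparison of assembled contigs.

The pipeline follows a four-stage design: (1) reciprocally best-matching
contig/chromosome pairs, (2) local alignments between the paired
sequences, (3) colinear chaining of the local alignments by dynamic
programming, (4) event calling from chain gaps with mechanism
classification (breakpoint flank homology: NAHR vs NHEJ) and inversion
detection.  An unpolarized indel (one genome has extra sequence) is
polarized with an outgroup: the two 2,500-bp flanks of the gap position in
the strain lacking the segment are mapped to the outgroup, and the
distance between the facing ends of the two flank alignments separates
insertions (distance near 0) from deletions (distance commensurate with
the event size).

Local alignments may be supplied externally in a tab format (see
:func:`read_alignments`) or produced by the built-in unique-k-mer
seed-and-extend aligner, which is adequate for assembled, moderately
diverged genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import align
from .align import encode, revcomp

log = logging.getLogger(__name__)

MID_SIZE_RANGE = (1_000, 50_000)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class LocalAlignment:
    """A gapless-equivalent local alignment block (1-based closed)."""

    query: str
    qstart: int
    qend: int
    target: str
    tstart: int
    tend: int
    strand: str                   # "+" | "-"
    identity: float
    score: float

    def __post_init__(self):
        if self.qstart > self.qend or self.tstart > self.tend:
            raise ValueError("alignment intervals must be non-empty")


@dataclass
class AlignmentChain:
    members: list[LocalAlignment]
    score: float
    strand: str

    def __post_init__(self):
        for u, v in zip(self.members, self.members[1:]):
            if v.qstart <= u.qend:
                raise ValueError("chain members must not overlap on the query")
            if u.strand == "+" and v.tstart <= u.tend:
                raise ValueError("chain members must not overlap on the target")
            if u.strand == "-" and v.tend >= u.tstart:
                raise ValueError("chain members must not overlap on the target")


@dataclass
class SVEvent:
    type: str                      # insertion | deletion | inversion | duplication
    carrier: str | None            # strain gaining (ins) / losing (del)
    chrom: str
    pos_query: int                 # 1-based first affected base on the query genome
    pos_target: int                # idem on the target genome
    size: int
    size_class: str = "mid"        # mid (1-50 kbp) | large
    mechanism: str = "unclassified"
    outgroup_distance: int | None = None
    extra_in: str | None = None    # which genome holds the extra sequence

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("event size must be positive")


# ---------------------------------------------------------------------------
# Reciprocal best pairing
# ---------------------------------------------------------------------------

def reciprocal_best_pairs(scores: dict) -> list[tuple]:
    """Reciprocally best matching pairs from a ``(a, b) -> score`` mapping.

    A pair survives iff b is a's unique best match and a is b's unique
    best; score ties eliminate both candidates (logged).
    """
    best_a: dict = {}
    best_b: dict = {}
    for (a, b), s in scores.items():
        for side, key, other in ((best_a, a, b), (best_b, b, a)):
            cur = side.get(key)
            if cur is None or s > cur[0]:
                side[key] = (s, other, False)
            elif s == cur[0] and other != cur[1]:
                side[key] = (s, cur[1], True)  # tie -> poisoned
    pairs = []
    for a, (s, b, tie_a) in sorted(best_a.items()):
        if tie_a:
            log.warning("tied best match for %s; dropped", a)
            continue
        sb, back, tie_b = best_b.get(b, (None, None, False))
        if tie_b:
            log.warning("tied best match for %s; dropped", b)
            continue
        if back == a:
            pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# Built-in aligner: unique k-mer anchors -> gapless blocks
# ---------------------------------------------------------------------------

def find_local_alignments(query, target, qname: str = "q", tname: str = "t",
                          k: int = 21, max_diag_jump: int = 30,
                          max_anchor_gap: int = 5_000,
                          min_anchors: int = 3) -> list[LocalAlignment]:
    """Colinear anchor blocks between two sequences, both strands.

    Anchors are k-mers unique in both sequences; a block is a maximal
    anchor run on a constant diagonal (tolerance ``max_diag_jump``) without
    anchor gaps above ``max_anchor_gap``.  Block identity is measured
    directly on the implied gapless alignment; score = matches - mismatches.
    """
    q = encode(query)
    t = encode(target)
    qp, tp, strand = align.anchors(q, t, k=k)
    out: list[LocalAlignment] = []
    for s in (1, -1):
        sel = strand == s
        if not np.any(sel):
            continue
        sq, st = qp[sel], tp[sel]
        order = np.argsort(sq, kind="stable")
        sq, st = sq[order], st[order]
        diag = st - sq if s == 1 else st + sq
        brk = np.nonzero((np.abs(np.diff(diag)) > max_diag_jump)
                         | (np.diff(sq) > max_anchor_gap))[0]
        starts = np.r_[0, brk + 1]
        ends = np.r_[brk + 1, sq.size]
        for a, b in zip(starts, ends):
            if b - a < min_anchors:
                continue
            d = int(np.median(diag[a:b]))
            qs, qe = int(sq[a]), int(sq[b - 1]) + k
            if s == 1:
                ts, te = qs + d, qe + d
                if ts < 0 or te > t.size:
                    qs, qe = max(qs, -d), min(qe, t.size - d)
                    ts, te = qs + d, qe + d
                qseg, tseg = q[qs:qe], t[ts:te]
            else:
                # anti-diagonal: tpos + qpos = d  (tpos of k-mer start on +)
                ts, te = d - qe + k, d - qs + k
                if ts < 0 or te > t.size:
                    continue
                qseg, tseg = q[qs:qe], revcomp(t[ts:te])
            n = min(qseg.size, tseg.size)
            if n == 0:
                continue
            matches = int(np.sum(qseg[:n] == tseg[:n]))
            identity = matches / n
            out.append(LocalAlignment(
                query=qname, qstart=qs + 1, qend=qs + n,
                target=tname,
                tstart=ts + 1, tend=ts + n,
                strand="+" if s == 1 else "-",
                identity=identity, score=float(2 * matches - n)))
    out.sort(key=lambda a: (a.qstart, a.tstart))
    return out


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def _gaps(u: LocalAlignment, v: LocalAlignment) -> tuple[int, int]:
    gq = v.qstart - u.qend - 1
    if u.strand == "+":
        gt = v.tstart - u.tend - 1
    else:
        gt = u.tstart - v.tend - 1
    return gq, gt


# Blocks built from k-mer anchors may overlap by up to ~k bp at a
# breakpoint (a seed ending exactly at the break belongs to either side);
# chaining tolerates such micro-overlaps.
OVERLAP_TOLERANCE = 50


def _colinear(u: LocalAlignment, v: LocalAlignment) -> bool:
    if u.strand != v.strand:
        return False
    if v.qstart <= u.qend - OVERLAP_TOLERANCE:
        return False
    if u.strand == "+":
        return v.tstart > u.tend - OVERLAP_TOLERANCE
    return v.tend < u.tstart + OVERLAP_TOLERANCE


def chain_alignments(alignments: list[LocalAlignment],
                     gap_cost: float = 0.01) -> AlignmentChain:
    """Maximum-score colinear chain by dynamic programming.

    Chain score = sum of member scores minus, for every adjacent pair, a
    gap penalty of ``gap_cost * (query gap + target gap)`` capped at the
    median member score of the input.  Plus- and minus-strand alignments
    are chained separately; the higher-scoring strand chain is returned
    (per-strand chains via :func:`chain_per_strand`).
    """
    chains = chain_per_strand(alignments, gap_cost=gap_cost)
    if not chains:
        raise ValueError("no alignments to chain")
    return max(chains.values(), key=lambda c: (c.score, c.strand))


def chain_per_strand(alignments: list[LocalAlignment],
                     gap_cost: float = 0.01) -> dict:
    if not alignments:
        return {}
    cap = float(np.median([a.score for a in alignments]))
    out = {}
    for strand in ("+", "-"):
        sub = sorted([a for a in alignments if a.strand == strand],
                     key=lambda a: (a.qstart, a.tstart))
        if not sub:
            continue
        n = len(sub)
        best = np.array([a.score for a in sub], dtype=float)
        prev = np.full(n, -1)
        for i in range(n):
            for j in range(i):
                if not _colinear(sub[j], sub[i]):
                    continue
                gq, gt = _gaps(sub[j], sub[i])
                pen = min(gap_cost * max(gq + gt, 0), cap)
                cand = best[j] + sub[i].score - pen
                if cand > best[i] + 1e-12:
                    best[i] = cand
                    prev[i] = j
        end = int(np.argmax(best))
        members = []
        i = end
        while i >= 0:
            members.append(sub[i])
            i = prev[i]
        members.reverse()
        out[strand] = AlignmentChain(members=_trim_overlaps(members),
                                     score=float(best[end]), strand=strand)
    return out


def _trim_overlaps(members: list[LocalAlignment]) -> list[LocalAlignment]:
    """Shrink seed-induced micro-overlaps so chain members are disjoint."""
    import dataclasses as _dc

    out: list[LocalAlignment] = []
    for m in members:
        if not out:
            out.append(m)
            continue
        u = out[-1]
        d_q = max(u.qend - m.qstart + 1, 0)
        if m.strand == "+":
            d_t = max(u.tend - m.tstart + 1, 0)
        else:
            d_t = max(m.tend - u.tstart + 1, 0)
        d = max(d_q, d_t)
        if d:
            if m.qstart + d > m.qend:
                log.info("chain member at q%d-%d swallowed by overlap trim",
                         m.qstart, m.qend)
                continue
            if m.strand == "+":
                m = _dc.replace(m, qstart=m.qstart + d, tstart=m.tstart + d)
            else:
                m = _dc.replace(m, qstart=m.qstart + d, tend=m.tend - d)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# Event calling
# ---------------------------------------------------------------------------

def call_svs(chain: AlignmentChain, alignments: list[LocalAlignment] | None = None,
             min_size: int = MID_SIZE_RANGE[0],
             mid_max: int = MID_SIZE_RANGE[1],
             chrom: str = "", query_seq=None, target_seq=None) -> list[SVEvent]:
    """Unpolarized events from the gaps of a colinear chain.

    For each adjacent chain pair the query gap g_q and target gap g_t are
    compared: |g_q - g_t| >= ``min_size`` yields an indel candidate whose
    extra sequence sits in the genome with the larger gap (mid class up to
    ``mid_max``, large beyond).  Opposite-strand alignments of at least
    ``min_size`` bp lying within the chain span are inversions; an
    inversion preserves length, so it may sit inside a single chain member
    (as an anchor hole) rather than inside a chain gap.  When both
    sequences are supplied, an indel candidate whose extra segment has a
    high-identity copy spanning the other genome's gap neighbourhood is
    reclassified as a duplication (carrier = the genome with the extra
    copy).
    """
    ms = chain.members
    for u, v in zip(ms, ms[1:]):
        if v.qstart <= u.qend:
            raise ValueError("overlapping chain members")
    span_q = (ms[0].qstart, ms[-1].qend)
    opposite = sorted((a for a in (alignments or [])
                       if a.strand != chain.strand
                       and span_q[0] - OVERLAP_TOLERANCE <= a.qstart
                       and a.qend <= span_q[1] + OVERLAP_TOLERANCE),
                      key=lambda a: a.qstart)
    events: list[SVEvent] = []
    # group nearby opposite-strand blocks (a fragmented inverted segment)
    groups: list[list[LocalAlignment]] = []
    for a in opposite:
        if groups and a.qstart - groups[-1][-1].qend <= 1_000:
            groups[-1].append(a)
        else:
            groups.append([a])
    for grp in groups:
        qs = min(a.qstart for a in grp)
        qe = max(a.qend for a in grp)
        size = qe - qs + 1
        if size < min_size:
            continue
        events.append(SVEvent(
            type="inversion", carrier=None, chrom=chrom,
            pos_query=qs, pos_target=min(a.tstart for a in grp),
            size=size,
            size_class="mid" if size <= mid_max else "large"))
    for u, v in zip(ms, ms[1:]):
        gq, gt = _gaps(u, v)
        if any(e.pos_query <= v.qstart and u.qend <= e.pos_query + e.size
               for e in events if e.type == "inversion"):
            continue  # gap explained by an inversion
        diff = gq - gt
        if abs(diff) < min_size:
            continue
        size = abs(diff)
        if diff > 0:
            extra = "query"
            pos_q = u.qend + 1 + max(gt, 0)
            pos_t = (u.tend + 1 if u.strand == "+" else u.tstart - 1)
        else:
            extra = "target"
            pos_q = u.qend + 1
            pos_t = (u.tend + 1 + max(gq, 0) if u.strand == "+"
                     else u.tstart - 1 - max(gq, 0))
        ev = SVEvent(
            type="indel", carrier=None, chrom=chrom,
            pos_query=pos_q, pos_target=pos_t, size=size,
            size_class="mid" if size <= mid_max else "large",
            extra_in=extra)
        if query_seq is not None and target_seq is not None:
            if _looks_duplicated(ev, u, v, query_seq, target_seq):
                ev.type = "duplication"
                ev.carrier = None  # genome named by extra_in until mapped
        events.append(ev)
    return events


def _looks_duplicated(ev: SVEvent, u: LocalAlignment, v: LocalAlignment,
                      query_seq, target_seq, k: int = 21) -> bool:
    """True when the extra segment maps near the other genome's gap site."""
    q = encode(query_seq)
    t = encode(target_seq)
    if ev.extra_in == "query":
        seg = q[u.qend:v.qstart - 1]
        other, pos_other = t, ev.pos_target
    else:
        if u.strand == "+":
            seg = t[u.tend:v.tstart - 1]
        else:
            seg = revcomp(t[v.tend:u.tstart - 1])
        other, pos_other = q, ev.pos_query
    lo = max(0, pos_other - 1 - 2 * ev.size)
    hi = min(other.size, pos_other - 1 + 2 * ev.size)
    window = other[lo:hi]
    qp, tp, strand = align.anchors(seg, window, k=k)
    best_span = 0
    for s in (1, -1):
        sel = strand == s
        if int(sel.sum()) < 10:
            continue
        diag = tp[sel] - qp[sel] if s == 1 else tp[sel] + qp[sel]
        med = np.median(diag)
        ok = np.abs(diag - med) <= 100
        if int(ok.sum()) < 10:
            continue
        span = int(qp[sel][ok].max() - qp[sel][ok].min()) + k
        best_span = max(best_span, span)
    return best_span >= 0.5 * ev.size


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------

def classify_mechanism(carrier_seq, start: int, end: int,
                       flank: int = 500, min_homology: int = 50,
                       min_identity: float = 0.8) -> str:
    """NAHR iff the two breakpoint flanks share a local alignment of at
    least ``min_homology`` bp at >= ``min_identity``; otherwise NHEJ.

    ``start``/``end`` delimit the event on the carrier genome (1-based
    closed).  Flanks truncated by a contig edge leave the event
    unclassified.
    """
    seq = encode(carrier_seq)
    ls, le = start - 1 - flank, start - 1
    rs, re = end, end + flank
    if ls < 0 or re > seq.size:
        return "unclassified"
    left, right = seq[ls:le], seq[rs:re]
    hits = align.local_hits(left, right, identity_floor=min_identity,
                            min_length=min_homology, max_hits=1)
    if hits:
        log.info("NAHR support: %d bp at %.2f identity",
                 hits[0]["length"], hits[0]["identity"])
        return "NAHR"
    return "NHEJ"


# ---------------------------------------------------------------------------
# Outgroup polarization
# ---------------------------------------------------------------------------

def polarize_with_outgroup(lacking_seq, gap_pos: int, size: int,
                           outgroup_seq, flank: int = 2_500,
                           k: int = 21):
    """Polarity of an indel via the outgroup state at the orthologous locus.

    ``lacking_seq`` is the genome without the extra segment, ``gap_pos``
    the 1-based position of the gap on it.  Both ``flank``-bp regions
    around the gap are mapped to the outgroup; the distance between the
    facing ends of the two mapped regions decides:

    - distance < max(500, 0.25 * size): the segment is absent from the
      outgroup as well -> "insertion" (into the strain carrying it);
    - 0.5 * size <= distance <= 2.0 * size: the outgroup retains a
      homologous segment -> "deletion" (from the lacking strain);
    - otherwise "unclassified".

    Returns ``(call, distance)``; distance is None when a flank fails to map.
    """
    nc = encode(lacking_seq)
    og = encode(outgroup_seq)
    p = gap_pos - 1
    if p - flank < 0 or p + flank > nc.size:
        return "unclassified", None
    left = align.project_interval(nc, og, p - flank, p, k=k)
    right = align.project_interval(nc, og, p, p + flank, k=k)
    if left is None or right is None:
        return "unclassified", None
    ls, le, lstrand, _ = left
    rs, re, rstrand, _ = right
    if lstrand != rstrand:
        log.warning("flanks map to opposite strands; unclassified")
        return "unclassified", None
    dist = (rs - le) if lstrand == 1 else (ls - re)
    if dist < -0.25 * flank:  # grossly inconsistent mapping
        return "unclassified", int(dist)
    dist = max(int(dist), 0)
    if dist < max(500, 0.25 * size):
        return "insertion", dist
    if 0.5 * size <= dist <= 2.0 * size:
        return "deletion", dist
    return "unclassified", dist


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def indel_balance_summary(events: list[SVEvent]) -> dict:
    """Counts and total lengths of insertions vs deletions per strain."""
    rows = []
    for ev in events:
        if ev.type in ("insertion", "deletion") and ev.carrier is not None:
            rows.append({"strain": ev.carrier, "type": ev.type,
                         "size": ev.size})
    if not rows:
        return {"table": pd.DataFrame(columns=["strain", "type", "count",
                                               "total_bp"]),
                "insertion_deletion_ratio": float("nan")}
    df = pd.DataFrame(rows)
    table = (df.groupby(["strain", "type"])
               .agg(count=("size", "size"), total_bp=("size", "sum"))
               .reset_index())
    n_ins = int((df["type"] == "insertion").sum())
    n_del = int((df["type"] == "deletion").sum())
    ratio = n_ins / n_del if n_del else float("nan")
    return {"table": table, "insertion_deletion_ratio": ratio,
            "n_insertions": n_ins, "n_deletions": n_del}


# ---------------------------------------------------------------------------
# Whole-pair driver
# ---------------------------------------------------------------------------

def compare_pair_with_outgroup(seq_a, seq_b, seq_out, chrom: str = "",
                               strain_a: str = "A", strain_b: str = "B",
                               k: int = 21, classify: bool = True,
                               min_size: int = MID_SIZE_RANGE[0]) -> list[SVEvent]:
    """Full SV pipeline for one chromosome pair plus outgroup.

    Aligns A (query) against B (target), chains, calls indel/inversion
    candidates and polarizes each indel with the outgroup; insertion
    carriers get a mechanism classification from their breakpoint flanks.
    """
    ea, eb, eo = encode(seq_a), encode(seq_b), encode(seq_out)
    alns = find_local_alignments(ea, eb, qname=strain_a, tname=strain_b, k=k)
    if not alns:
        return []
    chain = chain_alignments(alns)
    events = call_svs(chain, alignments=alns, chrom=chrom, min_size=min_size,
                      query_seq=ea, target_seq=eb)
    out = []
    for ev in events:
        if ev.type != "indel":
            out.append(ev)
            continue
        if ev.extra_in == "query":
            holder, holder_seq = strain_a, ea
            lack_seq, gap_pos = eb, ev.pos_target
            holder_pos = ev.pos_query
        else:
            holder, holder_seq = strain_b, eb
            lack_seq, gap_pos = ea, ev.pos_query
            holder_pos = ev.pos_target
        lacking = strain_b if holder == strain_a else strain_a
        call, dist = polarize_with_outgroup(lack_seq, gap_pos, ev.size, eo)
        ev.outgroup_distance = dist
        if call == "insertion":
            ev.type = "insertion"
            ev.carrier = holder
        elif call == "deletion":
            ev.type = "deletion"
            ev.carrier = lacking
        else:
            out.append(ev)
            continue
        if classify:
            ev.mechanism = classify_mechanism(holder_seq, holder_pos,
                                              holder_pos + ev.size - 1)
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = ["query", "qstart", "qend", "target", "tstart", "tend",
                     "strand", "identity", "score"]


def read_alignments(path: str) -> list[LocalAlignment]:
    """Read local alignments from a tab file with columns
    query qstart qend target tstart tend strand identity score
    (1-based closed intervals, as written by :func:`write_alignments`)."""
    df = pd.read_csv(path, sep="\t")
    return [LocalAlignment(**{c: row[c] for c in ALIGNMENT_COLUMNS})
            for _, row in df.iterrows()]


def write_alignments(alignments: list[LocalAlignment], path: str) -> None:
    pd.DataFrame([vars(a) for a in alignments])[ALIGNMENT_COLUMNS].to_csv(
        path, sep="\t", index=False)


def events_to_frame(events: list[SVEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events])
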