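"""Regulatory statistics at TSS-proximal insertions.

A transcription start site (TSS) qualifies for the paired analysis when
one strain carries a mid-sized (1-10 kbp) insertion within 100 bp of the
TSS and the orthologous region of the other strain does not.  For every
such pair, three quantities are computed in the 500-bp window upstream of
the (pseudo-)TSS — GC ratio, CpG-dinucleotide ratio, and the fraction of
unmethylated CpG calls — and the increase at the insertion-bearing TSS is
tested with one-sided Wilcoxon signed-rank tests over the matched pairs.
A simple negative-binomial two-group screen (median-of-ratios size
factors, method-of-moments dispersion, Wald p-value) stands in for a full
differential-expression stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import encode, revcomp

log = logging.getLogger(__name__)

UPSTREAM_WINDOW = 500
INSERTION_SIZE_RANGE = (1_000, 10_000)
MAX_TSS_DISTANCE = 100
TE_COVER_THRESHOLD = 0.30


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class TSSRecord:
    """A transcription start site with 5'-end tag support.

    ``position`` is 1-based; ``strand`` gives the transcript direction, so
    "upstream" means lower coordinates on "+" and higher on "-".
    """

    strain: str
    chromosome: str
    position: int
    strand: str
    tag_count: int = 1

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


@dataclass
class InsertionAtTSS:
    """A qualifying insertion next to a TSS (intervals 1-based closed)."""

    tss: TSSRecord
    insertion_start: int
    insertion_end: int
    distance: int                  # bp between the nearer breakpoint and the TSS
    te_class: str | None = None

    def __post_init__(self):
        size = self.size
        lo, hi = INSERTION_SIZE_RANGE
        if not lo <= size <= hi:
            raise ValueError(
                f"insertion size {size} outside [{lo}, {hi}] bp")
        if not 0 <= self.distance <= MAX_TSS_DISTANCE:
            raise ValueError(
                f"distance {self.distance} outside [0, {MAX_TSS_DISTANCE}] bp")

    @property
    def size(self) -> int:
        return self.insertion_end - self.insertion_start + 1


@dataclass
class WindowStats:
    """Sequence/methylation summary of the upstream window of one TSS."""

    gc_ratio: float
    cpg_ratio: float
    unmethylated_fraction: float   # NaN when no CpG in the window has a call
    window_start: int              # 1-based closed, on the forward strand
    window_end: int
    clipped: bool = False

    def __post_init__(self):
        for name in ("gc_ratio", "cpg_ratio", "unmethylated_fraction"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Pairing TSSs with insertions
# ---------------------------------------------------------------------------

def _interval_distance(start: int, end: int, pos: int) -> int:
    """Bases strictly between a closed interval and a position (0 if inside)."""
    if pos < start:
        return start - pos - 1
    if pos > end:
        return pos - end - 1
    return 0


def find_insertion_tss_pairs(tss_table: pd.DataFrame, insertions,
                             max_distance: int = MAX_TSS_DISTANCE,
                             size_range: tuple = INSERTION_SIZE_RANGE,
                             ) -> tuple[list[InsertionAtTSS], list[TSSRecord]]:
    """Match TSSs to nearby mid-sized insertions present in only one strain.

    ``tss_table`` holds one row per (tss_id, strain) with columns
    ``tss_id, strain, chrom, pos, strand, tag_count``; rows sharing a
    ``tss_id`` are orthologous loci, so the other strain's row is the
    pseudo-TSS of the pair.  ``insertions`` are polarized events with
    attributes ``type`` ("insertion"), ``carrier``, ``chrom``,
    ``pos_query`` (1-based start on the carrier genome) and ``size``.

    Returns the qualifying insertion-bearing TSSs and, position-matched,
    the counterpart pseudo-TSSs without an insertion.  TSSs without tag
    support, without a counterpart row, or with qualifying insertions in
    both strains are skipped (logged).
    """
    ins_by = {}
    for ev in insertions:
        if getattr(ev, "type", None) != "insertion" or ev.carrier is None:
            continue
        ins_by.setdefault((ev.carrier, str(ev.chrom)), []).append(ev)

    with_ins: list[InsertionAtTSS] = []
    partners: list[TSSRecord] = []
    for tss_id, grp in tss_table.groupby("tss_id"):
        rows = {r["strain"]: r for _, r in grp.iterrows()}
        if len(rows) < 2:
            log.warning("TSS %s has no counterpart region; skipped", tss_id)
            continue
        hits = {}
        for strain, row in rows.items():
            if int(row["tag_count"]) < 1:
                continue
            best = None
            for ev in ins_by.get((strain, str(row["chrom"])), []):
                if not size_range[0] <= ev.size <= size_range[1]:
                    continue
                start = int(ev.pos_query)
                end = start + ev.size - 1
                d = _interval_distance(start, end, int(row["pos"]))
                if d > max_distance:
                    continue
                if best is None or d < best[0]:
                    best = (d, start, end)
            if best is not None:
                hits[strain] = best
        if len(hits) != 1:
            if len(hits) == 2:
                log.info("TSS %s has insertions in both strains; skipped",
                         tss_id)
            continue
        strain = next(iter(hits))
        other = next(s for s in rows if s != strain)
        if int(rows[other]["tag_count"]) < 1:
            continue
        d, start, end = hits[strain]
        r = rows[strain]
        with_ins.append(InsertionAtTSS(
            tss=TSSRecord(strain=strain, chromosome=str(r["chrom"]),
                          position=int(r["pos"]), strand=str(r["strand"]),
                          tag_count=int(r["tag_count"])),
            insertion_start=start, insertion_end=end, distance=d))
        ro = rows[other]
        partners.append(TSSRecord(
            strain=other, chromosome=str(ro["chrom"]),
            position=int(ro["pos"]), strand=str(ro["strand"]),
            tag_count=int(ro["tag_count"])))
    return with_ins, partners


# ---------------------------------------------------------------------------
# Upstream window statistics
# ---------------------------------------------------------------------------

def window_stats(genome, tss: TSSRecord, methylation=None,
                 window: int = UPSTREAM_WINDOW) -> WindowStats:
    """GC ratio, CpG ratio and unmethylated-CpG fraction upstream of a TSS.

    The window covers the ``window`` bases 5' of the TSS: positions
    ``tss-window .. tss-1`` on the "+" strand, ``tss+1 .. tss+window``
    reverse-complemented on the "-" strand.  ``methylation`` maps 0-based
    forward-strand positions of CpG cytosines to a boolean (True =
    methylated); CpGs without an entry are excluded from the fraction's
    denominator.  A window truncated by the contig edge is flagged
    ``clipped``; a window entirely off-contig is an error.
    """
    seq = encode(genome)
    p0 = tss.position - 1                       # 0-based TSS
    if tss.strand == "+":
        lo, hi = p0 - window, p0                # half-open on forward
    else:
        lo, hi = p0 + 1, p0 + 1 + window
    clo, chi = max(lo, 0), min(hi, seq.size)
    if chi <= clo:
        raise ValueError("upstream window lies entirely off the contig")
    win = seq[clo:chi]
    if tss.strand == "-":
        win = revcomp(win)
    n = win.size
    gc = float(np.mean((win == 1) | (win == 2)))
    if n > 1:
        cpg = float(np.sum((win[:-1] == 1) & (win[1:] == 2))) / (n - 1)
    else:
        cpg = 0.0
    # CpG cytosine positions on the forward strand inside the window
    fwd = seq[clo:chi]
    c_pos = np.nonzero((fwd[:-1] == 1) & (fwd[1:] == 2))[0] + clo
    unmeth = float("nan")
    if methylation is not None:
        called = [methylation[p] for p in c_pos if p in methylation]
        if called:
            unmeth = 1.0 - float(np.mean(called))
    return WindowStats(gc_ratio=gc, cpg_ratio=cpg,
                       unmethylated_fraction=unmeth,
                       window_start=clo + 1, window_end=chi,
                       clipped=(clo != lo or chi != hi))


def calls_to_lookup(calls: pd.DataFrame, chrom=None) -> dict:
    """0-based position -> methylated? mapping from a CpG-call frame
    (columns ``chrom, pos, state``), optionally restricted to one chromosome."""
    df = calls if chrom is None else calls[calls["chrom"] == chrom]
    return dict(zip(df["pos"].astype(int),
                    (df["state"] == "methylated").to_numpy()))


# ---------------------------------------------------------------------------
# Paired one-sided tests
# ---------------------------------------------------------------------------

PAIRED_PARAMETERS = ("gc_ratio", "cpg_ratio", "unmethylated_fraction")


def paired_increase_tests(with_stats: list[WindowStats],
                          without_stats: list[WindowStats],
                          min_pairs: int = 6) -> pd.DataFrame:
    """One-sided Wilcoxon signed-rank tests for an increase at the
    insertion-bearing member of each matched pair.

    Each of ``gc_ratio``, ``cpg_ratio`` and ``unmethylated_fraction`` is
    tested with alternative "greater" (a higher unmethylated fraction is a
    lower methylation level, matching the expected decrease in
    methylation).  Pairs where either value is missing and zero-difference
    pairs are dropped; a parameter with no non-zero differences gets a NaN
    p-value.  Fewer than ``min_pairs`` matched pairs is an error.
    """
    if len(with_stats) != len(without_stats):
        raise ValueError("paired stat lists differ in length")
    if len(with_stats) < min_pairs:
        raise ValueError(
            f"need at least {min_pairs} matched pairs, got {len(with_stats)}")
    rows = []
    for param in PAIRED_PARAMETERS:
        a = np.array([getattr(s, param) for s in with_stats], dtype=float)
        b = np.array([getattr(s, param) for s in without_stats], dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        diff = a[ok] - b[ok]
        nz = diff[diff != 0.0]
        if nz.size == 0:
            p = float("nan")
            stat = float("nan")
        else:
            method = "exact" if nz.size <= 25 else "approx"
            res = stats.wilcoxon(nz, alternative="greater",
                                 zero_method="wilcox", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        log.info("%s: n=%d non-zero pairs, one-sided p=%.3g",
                 param, nz.size, p)
        rows.append({"parameter": param, "n_pairs": int(ok.sum()),
                     "n_nonzero": int(nz.size), "statistic": stat,
                     "p_value": p, "alternative": "greater"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transposable-element classification
# ---------------------------------------------------------------------------

def te_classify(insertion_length: int, annotations,
                threshold: float = TE_COVER_THRESHOLD) -> str | None:
    """TE family covering the largest fraction of the insertion, if > 30%.

    ``annotations`` is an iterable of ``(family, start, end)`` with 1-based
    closed intervals on the insertion sequence; intervals of one family are
    merged before measuring coverage.  Exactly 30% does not qualify
    (strict inequality).
    """
    if insertion_length <= 0:
        raise ValueError("insertion length must be positive")
    per_family: dict[str, list] = {}
    for fam, start, end in annotations:
        s = max(1, int(start))
        e = min(insertion_length, int(end))
        if e >= s:
            per_family.setdefault(fam, []).append((s, e))
    best_fam, best_cov = None, 0.0
    for fam, ivs in sorted(per_family.items()):
        ivs.sort()
        covered, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s + 1
        frac = covered / insertion_length
        if frac > best_cov:
            best_fam, best_cov = fam, frac
    return best_fam if best_cov > threshold else None


# ---------------------------------------------------------------------------
# Expression screen
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (rows loci, columns samples).

    Ratios are taken against the geometric mean over samples, using only
    loci expressed in every sample.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be loci x samples")
    pos = np.all(counts > 0, axis=1)
    if not np.any(pos):
        raise ValueError("no locus expressed in all samples")
    sub = counts[pos]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    return np.exp(np.median(np.log(sub) - log_gm, axis=0))


def expression_screen(counts: pd.DataFrame, strain_a: str,
                      strain_b: str) -> pd.DataFrame:
    """Per-locus two-group comparison of replicated counts.

    ``counts`` is long-form with columns ``tss_id, strain, replicate,
    count``.  After median-of-ratios normalization the two groups are
    compared under a negative-binomial model: a shared method-of-moments
    dispersion, Wald statistic on the log-fold-change ``strain_a`` vs
    ``strain_b``.  Per locus the result carries ``log2_fold_change``,
    ``p_value`` (NaN for all-zero loci) and ``novel`` (both ``strain_b``
    replicates zero, ``strain_a`` expressed).
    """
    wide = counts.pivot_table(index="tss_id", columns=["strain", "replicate"],
                              values="count", aggfunc="sum")
    cols_a = [c for c in wide.columns if c[0] == strain_a]
    cols_b = [c for c in wide.columns if c[0] == strain_b]
    if not cols_a or not cols_b:
        raise ValueError(f"missing counts for {strain_a!r} or {strain_b!r}")
    mat = wide[cols_a + cols_b].to_numpy(dtype=float)
    sf = size_factors(mat)
    norm = mat / sf
    na, nb = len(cols_a), len(cols_b)
    a, b = norm[:, :na], norm[:, na:]

    # method-of-moments dispersion, pooled over loci: Var = mu + disp * mu^2
    num = den = 0.0
    for grp, n in ((a, na), (b, nb)):
        if n < 2:
            continue
        mu_g = grp.mean(axis=1)
        ss = np.sum((grp - mu_g[:, None]) ** 2, axis=1)
        ok = mu_g > 0
        num += float(np.sum(ss[ok] - (n - 1) * mu_g[ok]))
        den += float(np.sum((n - 1) * mu_g[ok] ** 2))
    disp = max(num / den, 1e-8) if den > 0 else 1e-8

    pseud = 0.5
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    lfc = np.log2(ma + pseud) - np.log2(mb + pseud)
    # Wald: var of log mean under NB, delta method
    var_a = (ma + disp * ma ** 2) / na
    var_b = (mb + disp * mb ** 2) / nb
    se = np.sqrt(var_a / np.maximum(ma + pseud, pseud) ** 2
                 + var_b / np.maximum(mb + pseud, pseud) ** 2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2 * stats.norm.sf(np.abs(z))
    all_zero = (mat.sum(axis=1) == 0)
    p = np.where(all_zero, np.nan, p)
    lfc = np.where(all_zero, np.nan, lfc)
    novel = (b.sum(axis=1) == 0) & (a.sum(axis=1) > 0)
    return pd.DataFrame({
        "tss_id": wide.index,
        "base_mean": norm.mean(axis=1),
        "log2_fold_change": lfc,
        "p_value": p,
        "novel": novel,
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def stats_to_frame(stats_list: list[WindowStats],
                   tss_list: list[TSSRecord]) -> pd.DataFrame:
    rows = []
    for ws, tss in zip(stats_list, tss_list):
        rows.append({"strain": tss.strain, "chrom": tss.chromosome,
                     "pos": tss.position, "strand": tss.strand,
                     **{k: getattr(ws, k) for k in PAIRED_PARAMETERS},
                     "clipped": ws.clipped})
    return pd.DataFrame(rows)
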