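"""Chromosome maps from genetic markers and naive-Bayes Hi-C anchoring.

Contigs carrying SNP genetic markers are ordered along chromosomes by the
median genetic position (cM) of their markers; a contig whose markers come
from two chromosomes is split between the discordant marker blocks.
Contigs without markers can be joined to mapped neighbours through
BAC/fosmid clone end pairs, or -- for orphan contigs -- assigned to a
chromosome with a naive-Bayes classifier over Hi-C contact counts

    p(c | a_1..a_C) = p(c) prod_i p(a_i | c) / Z

with the prior p(c) proportional to the number of mapped contigs on
chromosome c, and then placed at the position of peak contact frequency
within the assigned chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

log = logging.getLogger(__name__)

CLONE_END_BOUNDS = {"BAC": 150_000, "fosmid": 50_000}
GAP_BETWEEN_CONTIGS = 1_000


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class GeneticMarker:
    marker_id: str
    chromosome: str
    cm: float
    contig: str
    offset: int                    # 1-based position on the contig

    def __post_init__(self):
        if self.offset < 1:
            raise ValueError(f"marker {self.marker_id}: offset must be >= 1")


@dataclass
class Placement:
    contig: str
    orientation: str               # "+", "-" or "?"
    source: str                    # marker | clone | hic | transfer
    cm: float | None = None


@dataclass
class ChromosomeMap:
    """Ordered contig placements per chromosome (1-kbp gap convention)."""

    chromosomes: dict = field(default_factory=dict)  # chrom -> [Placement]
    orphans: list[str] = field(default_factory=list)
    misassemblies: list[dict] = field(default_factory=list)

    def placed_contigs(self) -> set:
        return {p.contig for ps in self.chromosomes.values() for p in ps}

    def to_frame(self, contig_lengths: dict | None = None) -> pd.DataFrame:
        """AGP-like table: chromosome, start, end, component, orientation,
        source, with 1-kbp gaps between neighbouring contigs."""
        rows = []
        for chrom in sorted(self.chromosomes):
            pos = 1
            for i, p in enumerate(self.chromosomes[chrom]):
                ln = (contig_lengths or {}).get(p.contig, 0)
                rows.append({"chromosome": chrom, "start": pos,
                             "end": pos + max(ln, 1) - 1, "component": p.contig,
                             "orientation": p.orientation, "source": p.source})
                pos += max(ln, 1) + GAP_BETWEEN_CONTIGS
        return pd.DataFrame(rows)


@dataclass
class ContactVector:
    contig: str
    counts: np.ndarray             # one count per chromosome

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")


@dataclass
class NBModel:
    chromosomes: list[str]
    log_prior: np.ndarray          # per chromosome
    profiles: np.ndarray           # per-chromosome contact composition (rows sum to 1)
    pseudocount: float


# ---------------------------------------------------------------------------
# Marker ordering
# ---------------------------------------------------------------------------

def order_contigs_by_markers(markers: list[GeneticMarker],
                             contig_lengths: dict) -> ChromosomeMap:
    """Place and order marker-bearing contigs along chromosomes.

    A contig with markers from exactly one chromosome is placed at the
    median cM of its markers; equal-cM ties order by contig id and are
    flagged unoriented.  A contig with markers from two chromosomes is
    split at the midpoint between the innermost discordant markers and
    each part placed on its chromosome.  Contigs without markers are
    reported as orphans.
    """
    by_contig: dict[str, list[GeneticMarker]] = {}
    for mk in markers:
        if mk.contig not in contig_lengths:
            raise ValueError(f"marker {mk.marker_id} references unknown "
                             f"contig {mk.contig}")
        if mk.offset > contig_lengths[mk.contig]:
            raise ValueError(f"marker {mk.marker_id}: offset beyond contig end")
        by_contig.setdefault(mk.contig, []).append(mk)

    cmap = ChromosomeMap()
    entries: dict[str, list] = {}

    def add(chrom, contig, cm, oriented):
        entries.setdefault(chrom, []).append((cm, contig, oriented))

    for contig, mks in by_contig.items():
        chroms = sorted({m.chromosome for m in mks})
        if len(chroms) == 1:
            cms = sorted(m.cm for m in mks)
            oriented = len(set(cms)) > 1
            add(chroms[0], contig, float(np.median(cms)), oriented)
        elif len(chroms) == 2:
            blocks = {c: [m.offset for m in mks if m.chromosome == c]
                      for c in chroms}
            # innermost discordant markers on the contig
            a_end = max(blocks[chroms[0]])
            b_start = min(blocks[chroms[1]])
            if a_end > b_start:  # blocks interleave the other way round
                a_end = max(blocks[chroms[1]])
                b_start = min(blocks[chroms[0]])
                chroms = chroms[::-1]
            split = (a_end + b_start) // 2
            cmap.misassemblies.append({"contig": contig, "split": split,
                                       "chromosomes": chroms})
            for part, chrom in zip((f"{contig}.1", f"{contig}.2"), chroms):
                cms = sorted(m.cm for m in mks if m.chromosome == chrom)
                add(chrom, part, float(np.median(cms)), len(set(cms)) > 1)
        else:
            raise ValueError(f"contig {contig} has markers from more than "
                             "two chromosomes")

    for chrom in sorted(entries):
        placed = sorted(entries[chrom], key=lambda t: (t[0], t[1]))
        cm_counts: dict[float, int] = {}
        for cm, _, _ in placed:
            cm_counts[cm] = cm_counts.get(cm, 0) + 1
        cmap.chromosomes[chrom] = [
            Placement(contig=c, cm=cm, source="marker",
                      orientation="+" if (oriented and cm_counts[cm] == 1)
                      else "?")
            for cm, c, oriented in placed]

    cmap.orphans = sorted(set(contig_lengths) - set(by_contig))
    return cmap


def drop_redundant_contigs(cmap: ChromosomeMap, containments: dict) -> ChromosomeMap:
    """Remove contigs whose interval is contained in another placed contig.

    ``containments`` maps contig -> containing contig (from whole-genome
    alignment); only contigs whose container is itself placed are dropped.
    """
    placed = cmap.placed_contigs()
    for chrom, ps in cmap.chromosomes.items():
        cmap.chromosomes[chrom] = [
            p for p in ps
            if not (p.contig in containments and containments[p.contig] in placed)]
    return cmap


# ---------------------------------------------------------------------------
# Clone-end linking
# ---------------------------------------------------------------------------

def link_by_clone_ends(cmap: ChromosomeMap, end_pairs: list[tuple],
                       contig_lengths: dict, min_pairs: int = 2) -> ChromosomeMap:
    """Join unplaced contigs next to placed ones via clone end pairs.

    ``end_pairs`` contains ``(contig_a, pos_a, contig_b, pos_b, clone_type)``
    with 1-based read positions.  A pair qualifies when both reads map
    within the clone type's distance bound of a contig end (BAC 150 kbp,
    fosmid 50 kbp).  Contig pairs supported by >= ``min_pairs`` qualifying
    pairs are joined adjacently; a contig pulled toward two different
    partners is left unplaced and the conflict reported.
    """
    support: dict[tuple, int] = {}
    for ca, pa, cb, pb, ctype in end_pairs:
        if ctype not in CLONE_END_BOUNDS:
            raise ValueError(f"unknown clone type {ctype!r}")
        bound = CLONE_END_BOUNDS[ctype]

        def near_end(contig, pos):
            ln = contig_lengths[contig]
            return min(pos - 1, ln - pos) <= bound

        if near_end(ca, pa) and near_end(cb, pb):
            key = tuple(sorted((ca, cb)))
            support[key] = support.get(key, 0) + 1

    links = [k for k, n in support.items() if n >= min_pairs]
    placed = cmap.placed_contigs()
    partner: dict[str, set] = {}
    for a, b in links:
        partner.setdefault(a, set()).add(b)
        partner.setdefault(b, set()).add(a)

    for a, b in links:
        unplaced, anchor = (a, b) if a not in placed else (b, a)
        if anchor not in placed or unplaced in placed:
            continue
        if len(partner[unplaced]) > 1:
            log.warning("clone-link conflict: %s connects to %s; left unplaced",
                        unplaced, sorted(partner[unplaced]))
            continue
        for chrom, ps in cmap.chromosomes.items():
            idx = [i for i, p in enumerate(ps) if p.contig == anchor]
            if idx:
                ps.insert(idx[0] + 1, Placement(contig=unplaced,
                                                orientation="?",
                                                source="clone"))
                placed.add(unplaced)
                if unplaced in cmap.orphans:
                    cmap.orphans.remove(unplaced)
                break
    return cmap


# ---------------------------------------------------------------------------
# Naive Bayes over Hi-C contacts
# ---------------------------------------------------------------------------

def fit_nb(vectors: list[ContactVector], labels: list[str],
           chromosomes: list[str], contig_lengths: dict | None = None,
           pseudocount: float = 1.0) -> NBModel:
    """Fit priors and per-chromosome contact profiles.

    Priors are proportional to the number of training contigs per
    chromosome.  Each chromosome's conditional profile is the mean contact
    composition of its contigs (optionally length-normalized first), with
    a pseudocount for smoothing; the observation model is Poisson with the
    contig's total contacts allocated by the profile.
    """
    chrom_idx = {c: i for i, c in enumerate(chromosomes)}
    n_c = len(chromosomes)
    counts = np.zeros(n_c)
    sums = np.zeros((n_c, n_c))
    for v, lab in zip(vectors, labels):
        if lab not in chrom_idx:
            raise ValueError(f"unknown chromosome label {lab!r}")
        w = v.counts.astype(float)
        if contig_lengths:
            w = w / max(contig_lengths.get(v.contig, 1), 1)
        counts[chrom_idx[lab]] += 1
        sums[chrom_idx[lab]] += w
    empty = [chromosomes[i] for i in range(n_c) if counts[i] == 0]
    if empty:
        raise ValueError(f"no training contigs for chromosome(s) {empty}")
    prof = sums + pseudocount
    prof /= prof.sum(axis=1, keepdims=True)
    prior = counts / counts.sum()
    return NBModel(chromosomes=list(chromosomes), log_prior=np.log(prior),
                   profiles=prof, pseudocount=pseudocount)


def classify_orphan(model: NBModel, vector: ContactVector):
    """Posterior over chromosomes for one contact vector.

    Log-domain Poisson likelihood per chromosome with rates
    ``total_contacts * profile``; the normalizer Z makes the posterior sum
    to one.  Returns ``(posterior array, argmax chromosome)``.
    """
    a = vector.counts.astype(float)
    if a.size != len(model.chromosomes):
        raise ValueError("contact vector length does not match the model")
    if np.any(a < 0):
        raise ValueError("negative contact counts")
    total = a.sum()
    if total == 0:
        post = np.exp(model.log_prior)
        return post, model.chromosomes[int(np.argmax(post))]
    lam = total * model.profiles          # (n_chrom, n_chrom)
    loglik = (a * np.log(lam) - lam - gammaln(a + 1)).sum(axis=1)
    logpost = model.log_prior + loglik
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    return post, model.chromosomes[int(np.argmax(post))]


def locate_orphan(track: np.ndarray, bin_size: int,
                  window: int = 50_000):
    """Peak-contact placement of an assigned orphan contig.

    ``track`` holds binned contact counts along the assigned chromosome.
    The sliding-window mean (window in bp) is computed and the contig is
    slated for insertion at the argmax window center; ties break leftmost
    and a flat track raises a low-confidence flag.
    Returns ``(position_bp, low_confidence)``.
    """
    t = np.asarray(track, dtype=float)
    if t.size == 0:
        raise ValueError("empty contact track")
    w = max(1, int(round(window / bin_size)))
    kernel = np.ones(w)
    # edge-corrected sliding mean: divide by the in-range window size
    sm = np.convolve(t, kernel, mode="same") \
        / np.convolve(np.ones_like(t), kernel, mode="same")
    best = int(np.argmax(sm))
    low_conf = bool(np.allclose(sm, sm[best]))
    if low_conf:
        log.warning("flat contact track; leftmost window chosen")
        best = 0
    return (best * bin_size + bin_size // 2, low_conf)


def orient_by_best_match(alignments: list[dict], score_floor: float = 0.0) -> str:
    """Orientation transfer from the best cross-strain alignment.

    ``alignments`` are dicts with ``score`` and ``strand``; below the score
    floor, or on an exact score tie between conflicting strands, the contig
    stays unoriented ("?").
    """
    usable = [a for a in alignments if a["score"] > score_floor]
    if not usable:
        return "?"
    best = max(a["score"] for a in usable)
    strands = {a["strand"] for a in usable if a["score"] == best}
    if len(strands) > 1:
        log.warning("conflicting equal-score orientations; left unoriented")
        return "?"
    return strands.pop()
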