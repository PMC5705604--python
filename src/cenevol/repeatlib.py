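"""Centromeric satellite monomer analysis.

Operations: monomer decomposition of tandem arrays, greedy identity
clustering with longest-member representatives, cross-chromosome
best-match association, rank-sum comparison of similarity distributions
between chromosome positional classes (acrocentric vs non-acrocentric),
representative-monomer scoring, satellite genomic fraction in long reads,
telomeric repeat detection and Ward family trees of representatives.

The central statistic is the monomer similarity

    similarity(a, b) = matched bases / length of the shorter monomer

with matched bases counted on a global alignment (match +1, mismatch -1,
gap -1), and distance = 1 - similarity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from . import align
from .align import decode, encode

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class SatelliteMonomer:
    """One monomer occurrence (1-based fully-closed interval)."""

    id: str
    strain: str
    chromosome: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"monomer {self.id}: start > end")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(f"monomer {self.id}: interval/sequence length mismatch")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MonomerCluster:
    id: str
    members: list[str]
    representative: str | None      # defined only when size > 10
    size: int


@dataclass
class CentromereRegion:
    strain: str
    chromosome: str
    start: int
    end: int
    positional_class: str           # "acro" | "nonacro"
    monomer_ids: list[str] = field(default_factory=list)


@dataclass
class SimilarityRecord:
    cluster_a: str
    cluster_b: str
    similarity: float
    category: str                   # AcroAcro | AcroNonAcro | NonAcroNonAcro

    @property
    def distance(self) -> float:
        return 1.0 - self.similarity


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def monomer_similarity(a, b) -> float:
    """Matched bases of the optimal global alignment divided by the length
    of the shorter monomer.  Symmetric; in [0, 1]; N never matches."""
    ea, eb = encode(a), encode(b)
    if ea.size == 0:
        raise ValueError("first operand is empty")
    if eb.size == 0:
        raise ValueError("second operand is empty")
    _, matches = align.global_alignment(ea, eb)
    return min(1.0, matches / min(ea.size, eb.size))


# ---------------------------------------------------------------------------
# Decomposition and clustering
# ---------------------------------------------------------------------------

def decompose_array(region_seq, template, min_fraction: float = 0.5):
    """Tile a tandem array into fixed-length monomer windows.

    The phase offset is chosen so the first few windows best match the
    template (Hamming identity); windows are then cut every ``len(template)``
    bases.  A trailing partial window is kept when it covers at least
    ``min_fraction`` of the monomer length.  Returns a list of
    ``(start, end)`` 0-based half-open intervals on the region.
    """
    seq = encode(region_seq)
    t = encode(template)
    m = t.size
    if seq.size < m:
        return []
    n_probe = min(3, seq.size // m - 1) or 1
    best_o, best_id = 0, -1.0
    for o in range(min(m, seq.size - m + 1)):
        ident = 0.0
        for i in range(n_probe):
            s = o + i * m
            if s + m > seq.size:
                break
            ident += float(np.mean(seq[s:s + m] == t))
        if ident > best_id:
            best_id, best_o = ident, o
    out = []
    if best_o >= min_fraction * m:
        out.append((0, best_o))
    pos = best_o
    while pos + m <= seq.size:
        out.append((pos, pos + m))
        pos += m
    if seq.size - pos >= min_fraction * m:
        out.append((pos, seq.size))
    return out


def monomers_from_region(region: CentromereRegion, region_seq, template,
                         strain: str = "", **kwargs) -> list[SatelliteMonomer]:
    """Decompose a centromeric region into SatelliteMonomer records."""
    tiles = decompose_array(region_seq, template, **kwargs)
    seq = decode(encode(region_seq))
    out = []
    for i, (s, e) in enumerate(tiles):
        out.append(SatelliteMonomer(
            id=f"{region.strain}_{region.chromosome}_m{i}",
            strain=strain or region.strain, chromosome=region.chromosome,
            start=region.start + s, end=region.start + e - 1,
            strand="+", sequence=seq[s:e]))
    return out


def cluster_monomers(monomers: list[SatelliteMonomer],
                     similarity_threshold: float = 0.90,
                     min_representative_size: int = 11) -> list[MonomerCluster]:
    """Greedy identity clustering of the monomers of one chromosome.

    Monomers are processed longest-first (ties by input order); each joins
    the first existing cluster whose current representative has similarity
    >= threshold, otherwise founds a new cluster.  The representative of a
    cluster is its longest member and is only reported for clusters with
    more than 10 members.
    """
    if not (0 < similarity_threshold <= 1):
        raise ValueError("similarity_threshold must lie in (0, 1]")
    order = sorted(range(len(monomers)),
                   key=lambda i: (-monomers[i].length, i))
    clusters: list[dict] = []
    for i in order:
        mon = monomers[i]
        placed = False
        for cl in clusters:
            rep = cl["rep"]
            if monomer_similarity(mon.sequence, rep.sequence) >= similarity_threshold:
                cl["members"].append(mon)
                placed = True
                break
        if not placed:
            clusters.append({"rep": mon, "members": [mon]})
    out = []
    for j, cl in enumerate(clusters):
        members = cl["members"]
        longest = max(members, key=lambda m: (m.length,))
        rep = longest.id if len(members) >= min_representative_size else None
        out.append(MonomerCluster(
            id=f"cl{j}", members=[m.id for m in members],
            representative=rep, size=len(members)))
    return out


# ---------------------------------------------------------------------------
# Best-match association and group comparison
# ---------------------------------------------------------------------------

def _category(class_a: str, class_b: str) -> str:
    pair = sorted([class_a, class_b])
    if pair == ["acro", "acro"]:
        return "AcroAcro"
    if pair == ["nonacro", "nonacro"]:
        return "NonAcroNonAcro"
    return "AcroNonAcro"


def best_match_associations(clusters_by_chrom: dict,
                            sequences: dict,
                            classes: dict) -> list[SimilarityRecord]:
    """Associate each cluster with its best-matching cluster on another
    chromosome.

    ``clusters_by_chrom`` maps chromosome -> list of MonomerCluster (only
    clusters with a representative participate); ``sequences`` maps
    monomer id -> sequence; ``classes`` maps chromosome -> positional
    class.  Each association is categorized by the classes of the two
    chromosomes; ties break toward the lowest (chromosome, cluster id)
    pair and are logged.
    """
    entries = []
    for chrom in sorted(clusters_by_chrom):
        for cl in clusters_by_chrom[chrom]:
            if cl.representative is not None:
                entries.append((chrom, cl))
    chroms = {c for c, _ in entries}
    if len(chroms) < 2:
        raise ValueError("need representative clusters on >= 2 chromosomes")
    records = []
    sim_cache: dict[tuple, float] = {}

    def _sim(rep_a, rep_b):
        key = (rep_a, rep_b) if rep_a <= rep_b else (rep_b, rep_a)
        if key not in sim_cache:
            sim_cache[key] = monomer_similarity(sequences[key[0]],
                                                sequences[key[1]])
        return sim_cache[key]

    for chrom, cl in entries:
        best = None
        for ochrom, ocl in entries:
            if ochrom == chrom:
                continue
            sim = _sim(cl.representative, ocl.representative)
            key = (-sim, str(ochrom), ocl.id)
            if best is None or key < best[0]:
                if best is not None and -key[0] == -best[0][0]:
                    log.info("best-match tie for %s/%s broken toward %s/%s",
                             chrom, cl.id, ochrom, ocl.id)
                best = (key, ochrom, ocl, sim)
        if best is None:
            log.warning("cluster %s/%s has no cross-chromosome candidate",
                        chrom, cl.id)
            continue
        _, ochrom, ocl, sim = best
        records.append(SimilarityRecord(
            cluster_a=f"{chrom}/{cl.id}", cluster_b=f"{ochrom}/{ocl.id}",
            similarity=sim,
            category=_category(classes[chrom], classes[ochrom])))
    return records


def compare_similarity_groups(records: list[SimilarityRecord]):
    """One-sided rank-sum tests of NonAcroNonAcro similarities against the
    other two categories (alternative: NonAcroNonAcro is lower).

    Returns a dict with group medians, sizes, per-comparison p-values and a
    long-format DataFrame ready for box plotting.
    """
    groups = {"AcroAcro": [], "AcroNonAcro": [], "NonAcroNonAcro": []}
    for r in records:
        groups[r.category].append(r.similarity)
    for name in ("NonAcroNonAcro",):
        if len(groups[name]) < 2:
            raise ValueError(f"group {name} has fewer than 2 records")
    pvals = {}
    nn = groups["NonAcroNonAcro"]
    for other in ("AcroAcro", "AcroNonAcro"):
        if len(groups[other]) < 2:
            raise ValueError(f"group {other} has fewer than 2 records")
        method = "exact" if len(nn) + len(groups[other]) <= 25 else "asymptotic"
        res = sps.mannwhitneyu(nn, groups[other], alternative="less",
                               method=method)
        pvals[f"NonAcroNonAcro<{other}"] = float(res.pvalue)
    summary = pd.DataFrame(
        [{"category": k, "similarity": v} for k, vals in groups.items()
         for v in vals])
    medians = {k: (float(np.median(v)) if v else float("nan"))
               for k, v in groups.items()}
    return {"p_values": pvals, "medians": medians,
            "sizes": {k: len(v) for k, v in groups.items()},
            "summary": summary}


# ---------------------------------------------------------------------------
# Representative scoring / satellite fraction / telomeres
# ---------------------------------------------------------------------------

def representative_score(monomer, regions, identity_floor: float = 0.7) -> float:
    """Sum over local hits of identity * alignment_length / monomer_length.

    Hits are non-overlapping local alignments of the monomer against each
    region with identity above ``identity_floor``.  The monomer with the
    maximum score over a region set is the class representative.
    """
    q = encode(monomer)
    if q.size == 0:
        raise ValueError("monomer is empty")
    score = 0.0
    for region in regions:
        for hit in align.local_hits(q, region, identity_floor=identity_floor):
            score += hit["identity"] * hit["length"] / q.size
    return score


def satellite_fraction(reads: list[tuple], monomer,
                       min_length: int = 1000, min_qv: float = 10.0,
                       identity_floor: float = 0.7) -> float:
    """Satellite-masked fraction of base pairs in quality-filtered reads.

    ``reads`` is a list of ``(sequence, mean_qv)``; reads must be strictly
    longer than ``min_length`` and have mean QV strictly above ``min_qv``.
    Masking is by non-overlapping local alignment to the monomer.
    """
    total = 0
    masked = 0
    for seq, qv in reads:
        e = encode(seq)
        if e.size <= min_length or qv <= min_qv:
            continue
        total += e.size
        for hit in align.local_hits(monomer, e, identity_floor=identity_floor):
            masked += hit["end"] - hit["start"]
    if total == 0:
        raise ValueError("no reads pass filters")
    return masked / total


_TELOMERE_UNIT = "TTAGGG"


def find_telomeric_repeats(sequence, min_copies: int = 3) -> list[tuple]:
    """Maximal tandem arrays of the vertebrate telomere unit TTAGGG.

    Both strands are scanned (reverse complement CCCTAA on the forward
    string).  Returns ``(start, end, strand, copies)`` tuples with 1-based
    closed coordinates.
    """
    s = decode(encode(sequence))
    out = []
    for unit, strand in ((_TELOMERE_UNIT, "+"),
                         (decode(align.revcomp(encode(_TELOMERE_UNIT))), "-")):
        pattern = re.compile(f"(?:{unit}){{{min_copies},}}")
        for mt in pattern.finditer(s):
            copies = (mt.end() - mt.start()) // len(unit)
            out.append((mt.start() + 1, mt.end(), strand, copies))
    return sorted(out)


def classify_centromere_position(start: int, end: int, chromosome_length: int,
                                 acro_fraction: float = 0.15) -> str:
    """acro iff the region midpoint lies within ``acro_fraction`` of the
    chromosome length from the nearer end (closed boundary).  Coordinates
    are 1-based closed."""
    if start < 1 or end > chromosome_length or start > end:
        raise ValueError("region lies outside the chromosome")
    mid = 0.5 * (start + end)
    dist = min(mid - 1, chromosome_length - mid)
    return "acro" if dist <= acro_fraction * chromosome_length else "nonacro"


# ---------------------------------------------------------------------------
# Family tree of representatives
# ---------------------------------------------------------------------------

def family_tree(representatives: dict):
    """Ward-linkage hierarchy of representative monomers.

    ``representatives`` maps label -> sequence.  Pairwise distance is
    1 - similarity; linkage follows the ward.D2 convention (squared
    distances inside the Lance-Williams update).  Returns
    ``(labels, linkage_matrix)``; cut with :func:`cut_tree`.
    """
    labels = sorted(representatives)
    if len(labels) < 2:
        raise ValueError("need >= 2 representatives")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - monomer_similarity(
                representatives[labels[i]], representatives[labels[j]])
    Z = sch.linkage(squareform(d, checks=False), method="ward")
    return labels, Z


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Group assignment for a k-group cut of a linkage matrix."""
    return sch.fcluster(Z, t=k, criterion="maxclust")
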