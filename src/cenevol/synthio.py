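"""Synthetic trio genomes with known ground truth.

The generator emulates a three-strain phylogeny in which an outgroup
lineage splits off before two ingroup strains separate (mirroring two
island populations plus a more distant continental one).  Each chromosome
carries one centromeric tandem array of satellite monomers; arrays on
non-acrocentric chromosomes may mutate faster than acrocentric ones, and
rare exchange events copy monomer blocks between acrocentric arrays.
Mid-sized insertions/deletions are planted on the ingroup branches only,
so an outgroup comparison can recover their polarity.  Hypomethylated
domains with chromosome-specific k-mer composition are planted inside the
otherwise hypermethylated centromeres, and a set of transcription start
sites receives insertion-linked up-regulation.

Every random draw flows from one master seed through named, per-stage
``numpy`` generators, so identical configurations give byte-identical
outputs.  Internally all coordinates are 0-based half-open; the writers
convert to the conventions of each file format.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import decode, encode, revcomp

STRAINS = ("ing1", "ing2", "out")
INGROUP = ("ing1", "ing2")

# branch lengths in units of one ingroup terminal branch; the outgroup
# branch is longer (its split predates the ingroup split)
BRANCH_OUT = 1.4
BRANCH_SHARED = 0.4
BRANCH_TERMINAL = 1.0

_STREAMS = {"plan": 0, "backbone": 1, "branches": 2, "sv": 3,
            "arrays": 4, "meth": 5, "hic": 6, "tss": 7}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TrioConfig:
    """Parameters of a synthetic trio.

    Defaults are desk-scale: six 1-Mbp chromosomes instead of 24 x ~30 Mbp,
    with 20-60 kbp centromeric arrays; everything scales up by
    configuration.  Divergence rates are substitutions/site on one ingroup
    terminal branch; the shared ingroup branch is 0.4x and the outgroup
    branch 1.4x as long.
    """

    seed: int = 0
    n_chromosomes: int = 6
    chrom_length: int = 1_000_000
    monomer_length: int = 171
    array_length_range: tuple[int, int] = (20_000, 60_000)
    acro_fraction: float = 0.5
    div_rate_acro: float = 0.01
    div_rate_nonacro: float = 0.02
    exchange_rate: float = 1.0
    n_insertions: int = 20
    n_deletions: int = 20
    sv_size_range: tuple[int, int] = (1_000, 50_000)
    hic_decay: float = 1e-4
    hic_depth: int = 2_000
    meth_hypo_domains_per_centromere: int = 2
    tss_count: int = 50
    tss_effect: float = 1.0
    # secondary knobs -------------------------------------------------------
    n_lineages: int = 3              # ancestral monomer families per genome
    monomer_jitter: float = 0.02     # per-copy divergence inside an array
    chrom_divergence: float = 0.05   # ancestral per-chromosome lineage drift
    n_inversions: int = 0
    nahr_fraction: float = 0.3       # planted indels flanked by a shared repeat
    missing_centromeres: int = 0     # chromosomes left without an array
    meth_hypo_domain_length: int = 3_000
    bisulfite_mean_coverage: float = 5.0
    bisulfite_error_rate: float = 0.05
    bisulfite_coverage_constant: bool = False
    smrt_error_rate: float = 0.0
    contigs_per_chromosome: int = 20
    hic_bin: int = 10_000
    hic_trans_distance: float | None = None  # default: chrom_length
    tss_background: int = 150
    tss_base_mean: float = 200.0
    tss_dispersion: float = 0.1
    tss_novel_fraction: float = 0.3
    sv_mechanism_repeat_length: int = 300
    exchange_block_range: tuple[int, int] = (5, 16)  # monomer copies, half-open

    def validate(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be > 0")
        if self.monomer_length <= 0:
            raise ValueError("monomer_length must be > 0")
        lo, hi = self.array_length_range
        if not (0 < lo <= hi <= self.chrom_length):
            raise ValueError("array_length_range must be within chrom_length")
        for name in ("div_rate_acro", "div_rate_nonacro"):
            r = getattr(self, name)
            if not (0 <= r < 0.75):
                raise ValueError(f"{name} must lie in [0, 0.75)")
        if not (0 <= self.acro_fraction <= 1):
            raise ValueError("acro_fraction must lie in [0, 1]")
        if self.exchange_rate < 0:
            raise ValueError("exchange_rate must be >= 0")
        slo, shi = self.sv_size_range
        if not (0 < slo <= shi):
            raise ValueError("sv_size_range must be positive and ordered")
        if min(self.n_insertions, self.n_deletions, self.n_inversions) < 0:
            raise ValueError("n_insertions/n_deletions/n_inversions must be >= 0")
        if self.hic_decay < 0:
            raise ValueError("hic_decay must be >= 0")
        if self.hic_depth <= 0:
            raise ValueError("hic_depth must be > 0")
        if self.missing_centromeres >= self.n_chromosomes:
            raise ValueError("missing_centromeres must leave >= 1 array")

    @property
    def trans_distance(self) -> float:
        return (self.chrom_length if self.hic_trans_distance is None
                else self.hic_trans_distance)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class CentromereTruth:
    chrom: int
    clazz: str                       # "acro" | "nonacro"
    start_anc: int                   # ancestor coordinates, 0-based
    length: int
    n_copies: int
    lineage_of_copy: np.ndarray      # lineage id per full monomer copy


@dataclass
class HypoDomainTruth:
    chrom: int
    offset: int                      # offset of the domain within the array
    length: int


@dataclass
class SVTruth:
    event_id: int
    carrier: str                     # strain gaining (insertion) / losing (deletion)
    type: str                        # "insertion" | "deletion" | "inversion"
    mechanism: str                   # "NHEJ" | "NAHR" | "na"
    chrom: int
    pos_anc: int                     # ancestor/outgroup coordinates
    size: int


@dataclass
class ExchangeTruth:
    strain: str
    donor_chrom: int
    recipient_chrom: int
    donor_copy: int
    recipient_copy: int
    n_copies: int


@dataclass
class ContigTruth:
    contig: str
    chrom: int
    start: int                       # on the focal strain genome
    end: int
    orientation: str


@dataclass
class TSSTruth:
    tss_id: int
    chrom: int
    pos_anc: int
    strand: str
    carrier: str | None              # strain with the upstream insertion
    insertion_size: int
    insertion_gap: int               # bp between insertion and TSS (<= 100)
    base_mean: float
    novel: bool


@dataclass
class TrioGroundTruth:
    """Everything planted in one synthetic trio."""

    config: TrioConfig
    topology: tuple = (("out",), ("ing1", "ing2"))
    classes: dict = field(default_factory=dict)          # chrom -> class
    centromeres: list[CentromereTruth] = field(default_factory=list)
    hypo_domains: list[HypoDomainTruth] = field(default_factory=list)
    svs: list[SVTruth] = field(default_factory=list)
    exchanges: list[ExchangeTruth] = field(default_factory=list)
    contigs: list[ContigTruth] = field(default_factory=list)
    tss: list[TSSTruth] = field(default_factory=list)
    lineages: list[np.ndarray] = field(default_factory=list)
    # per (strain, chrom): (breakpoints in ancestor coords, cumulative delta)
    offset_maps: dict = field(default_factory=dict)

    def map_position(self, strain: str, chrom: int, pos: int) -> int:
        """Map an ancestor coordinate to final strain coordinates."""
        key = (strain, chrom)
        if key not in self.offset_maps:
            return pos
        breaks, delta = self.offset_maps[key]
        i = int(np.searchsorted(breaks, pos, side="right")) - 1
        return pos + int(delta[i])

    def centromere_interval(self, strain: str, chrom: int):
        """(start, end) of the array on a strain genome, or None."""
        for cen in self.centromeres:
            if cen.chrom == chrom:
                s = self.map_position(strain, chrom, cen.start_anc)
                return s, s + cen.length
        return None

    def hypo_domain_intervals(self, strain: str, chrom: int):
        out = []
        for cen in self.centromeres:
            if cen.chrom != chrom:
                continue
            s = self.map_position(strain, chrom, cen.start_anc)
            for d in self.hypo_domains:
                if d.chrom == chrom:
                    out.append((s + d.offset, s + d.offset + d.length))
        return out


@dataclass
class Trio:
    config: TrioConfig
    genomes: dict                    # strain -> {chrom index -> uint8 array}
    truth: TrioGroundTruth

    def sequence(self, strain: str, chrom: int) -> np.ndarray:
        return self.genomes[strain][chrom]


# ---------------------------------------------------------------------------
# Mutation and edit machinery
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. per-site substitution: each hit site moves to one of the
    other three bases uniformly (Jukes-Cantor-like, no indels)."""
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def _apply_edits(seq: np.ndarray, edits: list[dict]):
    """Apply insertion/deletion/inversion edits given in ancestor coords.

    ``edits`` must be non-overlapping.  Returns the edited sequence and the
    offset map ``(breakpoints, cumulative deltas)``.
    """
    edits = sorted(edits, key=lambda e: e["pos"])
    parts = []
    breaks = [0]
    deltas = [0]
    cur = 0
    delta = 0
    for e in edits:
        if e["kind"] == "ins":
            parts.append(seq[cur:e["pos"]])
            parts.append(e["seq"])
            cur = e["pos"]
            delta += len(e["seq"])
            breaks.append(e["pos"])
            deltas.append(delta)
        elif e["kind"] == "del":
            parts.append(seq[cur:e["pos"]])
            cur = e["pos"] + e["size"]
            delta -= e["size"]
            breaks.append(cur)
            deltas.append(delta)
        elif e["kind"] == "inv":
            parts.append(seq[cur:e["pos"]])
            parts.append(revcomp(seq[e["pos"]:e["pos"] + e["size"]]))
            cur = e["pos"] + e["size"]
        else:  # pragma: no cover
            raise ValueError(f"unknown edit kind {e['kind']!r}")
    parts.append(seq[cur:])
    return np.concatenate(parts), (np.asarray(breaks), np.asarray(deltas))


# ---------------------------------------------------------------------------
# Planning
# ---------------------------------------------------------------------------

def _plan_positions(rng, n, lo, hi, forbidden, min_gap):
    """Draw ``n`` positions in [lo, hi) keeping ``min_gap`` from each other
    and from the (start, end) intervals in ``forbidden``."""
    chosen: list[int] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > 200 * max(n, 1) + 1000:
            raise ValueError(
                "could not place all planted features; the chromosome is too "
                "crowded for the requested event counts/sizes")
        p = int(rng.integers(lo, hi))
        if any(s - min_gap < p < e + min_gap for s, e in forbidden):
            continue
        if any(abs(p - q) < min_gap for q in chosen):
            continue
        chosen.append(p)
    return sorted(chosen)


def _plan(config: TrioConfig, rng: np.random.Generator, truth: TrioGroundTruth):
    """Decide chromosome classes, array intervals, hypo domains, SV and TSS
    placements -- everything positional, before any sequence exists."""
    n = config.n_chromosomes
    L = config.chrom_length
    n_acro = int(round(config.acro_fraction * n))
    order = rng.permutation(n)
    acro_set = set(int(c) for c in order[:n_acro])
    truth.classes = {c: ("acro" if c in acro_set else "nonacro")
                     for c in range(n)}

    skip = set(int(c) for c in order[::-1][:config.missing_centromeres])
    m = config.monomer_length
    for c in range(n):
        if c in skip:
            continue
        alen = int(rng.integers(config.array_length_range[0],
                                config.array_length_range[1] + 1))
        alen = min(alen, L - 4000)
        mid = int(0.08 * L) if truth.classes[c] == "acro" else L // 2
        start = int(np.clip(mid - alen // 2, 2000, L - alen - 2000))
        n_copies = alen // m
        truth.centromeres.append(CentromereTruth(
            chrom=c, clazz=truth.classes[c], start_anc=start, length=alen,
            n_copies=n_copies, lineage_of_copy=np.empty(0, dtype=int)))
        # hypo domains inside the array, clear of its edges
        dlen = config.meth_hypo_domain_length
        k = config.meth_hypo_domains_per_centromere
        if k > 0 and alen > 2 * 500 + k * (dlen + 500):
            offs = _plan_positions(rng, k, 500, alen - 500 - dlen,
                                   [], dlen + 500)
            for o in offs:
                truth.hypo_domains.append(HypoDomainTruth(c, int(o), dlen))

    arrays = {cen.chrom: (cen.start_anc, cen.start_anc + cen.length)
              for cen in truth.centromeres}

    # --- SVs on ingroup terminal branches ---------------------------------
    ev_id = 0
    sv_plan = {s: [] for s in INGROUP}
    slo, shi = config.sv_size_range
    occupied = {c: [arrays.get(c, (0, 0))] for c in range(n)}
    kinds = ([("insertion", config.n_insertions),
              ("deletion", config.n_deletions),
              ("inversion", config.n_inversions)])
    for strain in INGROUP:
        for kind, count in kinds:
            for _ in range(count):
                # log-uniform sizes: mid-sized SVs are dominated by the
                # small end in real data
                size = int(np.exp(rng.uniform(np.log(slo), np.log(shi))))
                for _try in range(4000):
                    c = int(rng.integers(0, n))
                    p = int(rng.integers(5000, L - 5000 - size))
                    span = (p - 4000, p + size + 4000)
                    if all(e <= span[0] or s >= span[1]
                           for s, e in occupied[c]):
                        break
                else:
                    raise ValueError(
                        "could not place all planted SVs; reduce counts or "
                        "sizes, or enlarge chrom_length")
                occupied[c].append((span[0], span[1]))
                occupied[c].sort()
                mech = "na"
                if kind in ("insertion", "deletion"):
                    mech = ("NAHR" if rng.random() < config.nahr_fraction
                            else "NHEJ")
                truth.svs.append(SVTruth(ev_id, strain, kind, mech, c, p, size))
                sv_plan[strain].append(truth.svs[-1])
                ev_id += 1

    # --- TSS loci ----------------------------------------------------------
    n_linked = config.tss_count
    n_all = n_linked + config.tss_background
    if n_all > 0:
        # chop the free space into 13-kbp slots (room for a 10-kbp
        # insertion plus the 500-bp upstream window on either side) and
        # sample slots without replacement
        slot = 13_000
        slots: list[tuple[int, int]] = []
        for c in range(n):
            busy = sorted(occupied[c])
            cur = 15_000
            for s, e in busy + [(L - 15_000, L)]:
                x = cur
                while x + slot <= s:
                    slots.append((c, x))
                    x += slot
                cur = max(cur, e)
        if len(slots) < n_all:
            raise ValueError(
                f"could not place all TSS loci ({n_all} requested, "
                f"{len(slots)} slots available)")
        picked = rng.choice(len(slots), size=n_all, replace=False)
        for i, si in enumerate(picked):
            c, x = slots[int(si)]
            p = x + slot // 2 + int(rng.integers(-500, 501))
            linked = i < n_linked
            carrier = INGROUP[int(rng.integers(0, 2))] if linked else None
            isize = int(rng.integers(1000, 10_001)) if linked else 0
            gap = int(rng.integers(0, 101)) if linked else 0
            novel = bool(linked and rng.random() < config.tss_novel_fraction)
            base = float(np.exp(rng.normal(np.log(config.tss_base_mean), 0.5)))
            truth.tss.append(TSSTruth(
                tss_id=i, chrom=c, pos_anc=p,
                strand="+" if rng.random() < 0.5 else "-",
                carrier=carrier, insertion_size=isize, insertion_gap=gap,
                base_mean=base, novel=novel))

    # --- contig map of the focal strain (ing1) ----------------------------
    for c in range(n):
        bounds = np.linspace(0, L, config.contigs_per_chromosome + 1,
                             dtype=int)
        for i in range(config.contigs_per_chromosome):
            truth.contigs.append(ContigTruth(
                contig=f"ctg_{c}_{i}", chrom=c,
                start=int(bounds[i]), end=int(bounds[i + 1]),
                orientation="+" if rng.random() < 0.5 else "-"))


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

_GC_RICH = np.array([0.16, 0.34, 0.34, 0.16])


def _random_seq(rng, n, probs=None):
    if probs is None:
        return rng.integers(0, 4, size=n, dtype=np.uint8)
    return rng.choice(4, size=n, p=probs).astype(np.uint8)


def generate_trio(config: TrioConfig) -> Trio:
    """Build the three genomes (backbone + planted SV/TSS edits) and the
    ground truth.  Centromeric arrays are planned here but their sequences
    are filled in by :func:`generate_centromere_arrays`."""
    config.validate()
    truth = TrioGroundTruth(config=config)
    _plan(config, _rng(config.seed, "plan"), truth)

    rng_b = _rng(config.seed, "backbone")
    rng_m = _rng(config.seed, "branches")
    rng_s = _rng(config.seed, "sv")

    n, L = config.n_chromosomes, config.chrom_length
    r = config.div_rate_acro  # backbone substitution rate per terminal branch
    genomes = {s: {} for s in STRAINS}
    rep_len = config.sv_mechanism_repeat_length

    for c in range(n):
        anc = _random_seq(rng_b, L)
        # NAHR-labelled events sit between two copies of a local repeat;
        # write the duplicated repeat into the ancestor so every strain
        # shares the homologous flanks
        for ev in truth.svs:
            if ev.chrom == c and ev.mechanism == "NAHR":
                rep = _random_seq(rng_s, rep_len)
                anc[ev.pos_anc - rep_len:ev.pos_anc] = rep
                if ev.type == "deletion":
                    anc[ev.pos_anc + ev.size:ev.pos_anc + ev.size + rep_len] = rep
                else:
                    anc[ev.pos_anc:ev.pos_anc + rep_len] = rep
        out_g = _mutate(anc, r * BRANCH_OUT, rng_m)
        ing_anc = _mutate(anc, r * BRANCH_SHARED, rng_m)
        branch = {s: _mutate(ing_anc, r * BRANCH_TERMINAL, rng_m)
                  for s in INGROUP}
        genomes["out"][c] = out_g
        for strain in INGROUP:
            edits = []
            for ev in truth.svs:
                if ev.carrier != strain or ev.chrom != c:
                    continue
                if ev.type == "insertion":
                    edits.append({"kind": "ins", "pos": ev.pos_anc,
                                  "seq": _random_seq(rng_s, ev.size)})
                elif ev.type == "deletion":
                    edits.append({"kind": "del", "pos": ev.pos_anc,
                                  "size": ev.size})
                else:
                    edits.append({"kind": "inv", "pos": ev.pos_anc,
                                  "size": ev.size})
            for t in truth.tss:
                if t.carrier != strain or t.chrom != c:
                    continue
                ins_seq = _random_seq(rng_s, t.insertion_size, probs=_GC_RICH)
                pos = (t.pos_anc - t.insertion_gap if t.strand == "+"
                       else t.pos_anc + 1 + t.insertion_gap)
                edits.append({"kind": "ins", "pos": pos, "seq": ins_seq})
            seq, omap = _apply_edits(branch[strain], edits)
            genomes[strain][c] = seq
            truth.offset_maps[(strain, c)] = omap
    return Trio(config=config, genomes=genomes, truth=truth)


def generate_centromere_arrays(trio: Trio) -> Trio:
    """Fill the planned centromeric arrays with satellite sequence.

    A small set of ancestral monomer lineages is shared by all
    chromosomes; each chromosome drifts its own lineage variants
    (chromosome segregation precedes strain divergence), each array copy
    carries light per-copy jitter, and strain arrays then mutate along the
    phylogeny at the class rate (acrocentric vs non-acrocentric).
    Hypomethylated domains are overwritten with sequence drawn from a
    chromosome-specific base composition, and exchange events copy monomer
    blocks between acrocentric arrays of the same strain.
    """
    config, truth = trio.config, trio.truth
    rng = _rng(config.seed, "arrays")
    m = config.monomer_length

    truth.lineages = [_random_seq(rng, m) for _ in range(config.n_lineages)]

    strain_arrays: dict[tuple[str, int], np.ndarray] = {}
    for cen in truth.centromeres:
        rate = (config.div_rate_acro if cen.clazz == "acro"
                else config.div_rate_nonacro)
        chrom_lin = [_mutate(t, config.chrom_divergence, rng)
                     for t in truth.lineages]
        # contiguous lineage blocks along the array
        lineage_of_copy = np.zeros(cen.n_copies, dtype=int)
        n_blocks = max(1, config.n_lineages)
        cuts = np.sort(rng.choice(np.arange(1, max(cen.n_copies, 2)),
                                  size=min(n_blocks - 1,
                                           max(cen.n_copies - 1, 0)),
                                  replace=False))
        lin_ids = rng.permutation(config.n_lineages)
        for b, (s, e) in enumerate(zip(np.r_[0, cuts],
                                       np.r_[cuts, cen.n_copies])):
            lineage_of_copy[s:e] = lin_ids[b % config.n_lineages]
        cen.lineage_of_copy = lineage_of_copy
        copies = [_mutate(chrom_lin[l], config.monomer_jitter, rng)
                  for l in lineage_of_copy]
        anc_array = np.concatenate(copies + [chrom_lin[lineage_of_copy[-1] if
                                                       cen.n_copies else 0]
                                             [:cen.length - m * cen.n_copies]])
        # ancestral hypo domains: chromosome-specific composition
        comp = rng.dirichlet([4.0, 6.0, 6.0, 4.0])
        for d in truth.hypo_domains:
            if d.chrom == cen.chrom:
                anc_array[d.offset:d.offset + d.length] = _random_seq(
                    rng, d.length, probs=comp)
        out_arr = _mutate(anc_array, rate * BRANCH_OUT, rng)
        ing_anc = _mutate(anc_array, rate * BRANCH_SHARED, rng)
        strain_arrays[("out", cen.chrom)] = out_arr
        for strain in INGROUP:
            strain_arrays[(strain, cen.chrom)] = _mutate(
                ing_anc, rate * BRANCH_TERMINAL, rng)

    # exchanges between acrocentric arrays (recent: after terminal mutation)
    acro_cens = [c for c in truth.centromeres if c.clazz == "acro"]
    if len(acro_cens) >= 2 and config.exchange_rate > 0:
        hypo_by_chrom: dict[int, list] = {}
        for d in truth.hypo_domains:
            hypo_by_chrom.setdefault(d.chrom, []).append(d)

        def _block_free(cen, i0, nb):
            s, e = i0 * m, (i0 + nb) * m
            return all(e <= d.offset or s >= d.offset + d.length
                       for d in hypo_by_chrom.get(cen.chrom, []))

        for strain in INGROUP:
            for _ in range(int(rng.poisson(config.exchange_rate))):
                for _try in range(200):
                    don, rec = rng.choice(len(acro_cens), size=2,
                                          replace=False)
                    don_c, rec_c = acro_cens[int(don)], acro_cens[int(rec)]
                    nb = int(rng.integers(*config.exchange_block_range))
                    if don_c.n_copies <= nb or rec_c.n_copies <= nb:
                        continue
                    di = int(rng.integers(0, don_c.n_copies - nb))
                    ri = int(rng.integers(0, rec_c.n_copies - nb))
                    if _block_free(don_c, di, nb) and _block_free(rec_c, ri, nb):
                        break
                else:
                    continue
                src = strain_arrays[(strain, don_c.chrom)]
                dst = strain_arrays[(strain, rec_c.chrom)]
                dst[ri * m:(ri + nb) * m] = src[di * m:(di + nb) * m]
                truth.exchanges.append(ExchangeTruth(
                    strain, don_c.chrom, rec_c.chrom, di, ri, nb))

    for (strain, chrom), arr in strain_arrays.items():
        cen = next(c for c in truth.centromeres if c.chrom == chrom)
        s = truth.map_position(strain, chrom, cen.start_anc)
        trio.genomes[strain][chrom][s:s + cen.length] = arr
    return trio


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def _cpg_positions(seq: np.ndarray) -> np.ndarray:
    """0-based positions of the C of every CpG on the forward strand."""
    return np.nonzero((seq[:-1] == 1) & (seq[1:] == 2))[0]


def _tss_insertion_intervals(trio: Trio, strain: str, chrom: int):
    """Final-coordinate intervals of TSS-linked insertions in ``strain``."""
    out = []
    for t in trio.truth.tss:
        if t.carrier != strain or t.chrom != chrom:
            continue
        pos = (t.pos_anc - t.insertion_gap if t.strand == "+"
               else t.pos_anc + 1 + t.insertion_gap)
        s = trio.truth.map_position(strain, chrom, pos - 1) + 1
        out.append((s, s + t.insertion_size))
    return out


def tss_insertion_events(trio: Trio):
    """Planted TSS-linked insertions as polarized insertion events.

    Each event carries ``type`` ("insertion"), ``carrier``, ``chrom``,
    ``pos_query`` (1-based start on the carrier genome) and ``size`` —
    the attributes the TSS-pairing stage expects, so truth-derived events
    can stand in for a structural-variant caller's output.
    """
    from types import SimpleNamespace

    out = []
    for t in trio.truth.tss:
        if t.carrier is None:
            continue
        (s, e), = [iv for iv in _tss_insertion_intervals(trio, t.carrier,
                                                         t.chrom)
                   if abs((iv[1] - iv[0]) - t.insertion_size) == 0
                   and _near(iv, trio, t)] or [(None, None)]
        if s is None:
            continue
        out.append(SimpleNamespace(type="insertion", carrier=t.carrier,
                                   chrom=t.chrom, pos_query=s + 1,
                                   size=e - s, tss_id=t.tss_id))
    return out


def _near(iv, trio: Trio, t: TSSTruth) -> bool:
    pos = trio.truth.map_position(t.carrier, t.chrom, t.pos_anc)
    return min(abs(iv[0] - pos), abs(iv[1] - pos)) <= t.insertion_gap + 2


@dataclass
class MethylationTracks:
    calls: dict           # strain -> DataFrame(chrom, pos, state)
    pileups: dict         # strain -> DataFrame(chrom, pos, meth_count, total_count)


def generate_methylation(trio: Trio, min_cpgs: int = 40) -> MethylationTracks:
    """Per-CpG methylation state tracks plus simulated bisulfite pileups.

    Background CpGs are methylated; CpGs inside planted hypomethylated
    centromere domains and inside TSS-linked insertions are unmethylated.
    Bisulfite coverage is Poisson (or constant) and each read reports the
    true state flipped with the configured error rate.  A planted domain
    whose sequence carries fewer than ``min_cpgs`` CpGs is rejected, since
    the downstream segmentation would never be able to recover it.
    """
    config, truth = trio.config, trio.truth
    rng = _rng(config.seed, "meth")
    calls, pileups = {}, {}
    for strain in STRAINS:
        frames = []
        for chrom in sorted(trio.genomes[strain]):
            seq = trio.genomes[strain][chrom]
            pos = _cpg_positions(seq)
            state = np.ones(pos.size, dtype=bool)  # True = methylated
            hypo_iv = truth.hypo_domain_intervals(strain, chrom)
            for i, (s, e) in enumerate(hypo_iv):
                inside = (pos >= s) & (pos < e)
                if int(inside.sum()) < min_cpgs:
                    raise ValueError(
                        f"hypomethylated domain {i} on chromosome {chrom} of "
                        f"{strain} has {int(inside.sum())} CpGs (< {min_cpgs})")
                state[inside] = False
            for s, e in _tss_insertion_intervals(trio, strain, chrom):
                state[(pos >= s) & (pos < e)] = False
            if config.smrt_error_rate > 0:
                flip = rng.random(pos.size) < config.smrt_error_rate
                state = state ^ flip
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos,
                "state": np.where(state, "methylated", "unmethylated")}))
        df = pd.concat(frames, ignore_index=True)
        calls[strain] = df

        if config.bisulfite_coverage_constant:
            cov = np.full(len(df), int(config.bisulfite_mean_coverage))
        else:
            cov = rng.poisson(config.bisulfite_mean_coverage, size=len(df))
        keep = cov > 0
        meth = df["state"].to_numpy() == "methylated"
        p = np.where(meth, 1 - config.bisulfite_error_rate,
                     config.bisulfite_error_rate)
        mc = rng.binomial(cov, p)
        pileups[strain] = pd.DataFrame({
            "chrom": df["chrom"].to_numpy()[keep],
            "pos": df["pos"].to_numpy()[keep],
            "meth_count": mc[keep],
            "total_count": cov[keep]})
    return MethylationTracks(calls=calls, pileups=pileups)


@dataclass
class HiCData:
    contacts: pd.DataFrame        # contigs x chromosomes count matrix
    tracks: dict                  # contig -> binned counts on its own chromosome
    bin_size: int


def generate_hic_contacts(trio: Trio) -> HiCData:
    """Hi-C contact counts per (contig, chromosome) plus per-contig binned
    contact tracks along the contig's true chromosome.

    Contact intensity decays exponentially with genomic distance from the
    contig's true position; inter-chromosomal contacts behave as if at a
    fixed large distance, so ``hic_decay=0`` degenerates to contacts
    proportional to chromosome length and a very large decay concentrates
    everything on the contig's own chromosome.
    """
    config, truth = trio.config, trio.truth
    rng = _rng(config.seed, "hic")
    n, L, b = config.n_chromosomes, config.chrom_length, config.hic_bin
    centers = np.arange(b // 2, L, b, dtype=float)
    n_bins = centers.size
    trans_w = float(np.exp(-config.hic_decay * config.trans_distance)) * n_bins

    rows, tracks = [], {}
    for ct in truth.contigs:
        mid = 0.5 * (ct.start + ct.end)
        w_own = np.exp(-config.hic_decay * np.abs(centers - mid))
        w = np.full(n, trans_w)
        w[ct.chrom] = float(w_own.sum())
        lam = config.hic_depth * w / w.sum()
        counts = rng.poisson(lam)
        lam_bins = lam[ct.chrom] * w_own / w_own.sum()
        track = rng.poisson(lam_bins)
        counts[ct.chrom] = int(track.sum())
        tracks[ct.contig] = track
        rows.append(counts)
    contacts = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, n), int),
                            index=[c.contig for c in truth.contigs],
                            columns=[f"chr{c + 1}" for c in range(n)])
    return HiCData(contacts=contacts, tracks=tracks, bin_size=b)


@dataclass
class TSSData:
    table: pd.DataFrame           # strain-wise TSS records
    counts: pd.DataFrame          # tss_id x (strain, replicate) counts


def generate_tss_counts(trio: Trio) -> TSSData:
    """TSS tables for the two ingroup strains plus two-replicate RNA counts.

    Counts are negative-binomial around a per-locus base mean; the carrier
    of an insertion-linked TSS multiplies its mean by ``exp(tss_effect)``.
    A ``novel`` locus is silent (zero mean) in the non-carrier strain.
    """
    config, truth = trio.config, trio.truth
    rng = _rng(config.seed, "tss")
    disp = config.tss_dispersion
    nb_n = 1.0 / disp

    rows, cnt_rows = [], []
    for t in truth.tss:
        for strain in INGROUP:
            pos = trio.truth.map_position(strain, t.chrom, t.pos_anc)
            rows.append({"tss_id": t.tss_id, "strain": strain,
                         "chrom": t.chrom, "pos": pos, "strand": t.strand,
                         "tag_count": int(rng.integers(5, 50))})
            mean = t.base_mean
            if t.carrier == strain:
                mean *= float(np.exp(config.tss_effect))
            elif t.novel:
                mean = 0.0
            for rep in (1, 2):
                if mean <= 0:
                    cnt = 0
                else:
                    p = nb_n / (nb_n + mean)
                    cnt = int(rng.negative_binomial(nb_n, p))
                cnt_rows.append({"tss_id": t.tss_id, "strain": strain,
                                 "replicate": rep, "count": cnt})
    return TSSData(table=pd.DataFrame(rows), counts=pd.DataFrame(cnt_rows))


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fasta(trio: Trio, outdir: str) -> list[str]:
    """One FASTA per strain, record IDs ``<strain>_chr<N>`` (N is 1-based)."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for strain in STRAINS:
        path = os.path.join(outdir, f"{strain}.fa")
        with open(path, "w") as fh:
            for chrom in sorted(trio.genomes[strain]):
                fh.write(f">{strain}_chr{chrom + 1}\n")
                s = decode(trio.genomes[strain][chrom])
                for i in range(0, len(s), 80):
                    fh.write(s[i:i + 80] + "\n")
        paths.append(path)
    return paths


def write_truth_beds(trio: Trio, outdir: str) -> None:
    """Centromeres, hypomethylated domains and SVs as 0-based BED."""
    os.makedirs(outdir, exist_ok=True)
    truth = trio.truth
    with open(os.path.join(outdir, "centromeres.bed"), "w") as fh:
        for strain in STRAINS:
            for cen in truth.centromeres:
                iv = truth.centromere_interval(strain, cen.chrom)
                fh.write(f"{strain}_chr{cen.chrom + 1}\t{iv[0]}\t{iv[1]}\t"
                         f"{cen.clazz}\n")
    with open(os.path.join(outdir, "hypo_domains.bed"), "w") as fh:
        for strain in STRAINS:
            for c in sorted({d.chrom for d in truth.hypo_domains}):
                for s, e in truth.hypo_domain_intervals(strain, c):
                    fh.write(f"{strain}_chr{c + 1}\t{s}\t{e}\thypo\n")
    with open(os.path.join(outdir, "svs.bed"), "w") as fh:
        for ev in truth.svs:
            fh.write(f"anc_chr{ev.chrom + 1}\t{ev.pos_anc}\t"
                     f"{ev.pos_anc + ev.size}\t"
                     f"{ev.type}:{ev.carrier}:{ev.mechanism}\n")


def write_methylation(tracks: MethylationTracks, outdir: str) -> None:
    """CpG calls and pileups as TSV with 1-based positions."""
    os.makedirs(outdir, exist_ok=True)
    for strain, df in tracks.calls.items():
        out = df.copy()
        out["pos"] = out["pos"] + 1
        out.to_csv(os.path.join(outdir, f"{strain}.cpg_calls.tsv"),
                   sep="\t", index=False)
    for strain, df in tracks.pileups.items():
        out = df.copy()
        out["pos"] = out["pos"] + 1
        out.to_csv(os.path.join(outdir, f"{strain}.bisulfite.tsv"),
                   sep="\t", index=False)


def write_hic(hic: HiCData, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    hic.contacts.to_csv(os.path.join(outdir, "hic_contacts.tsv"), sep="\t")


def write_tss(tss: TSSData, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    tss.table.to_csv(os.path.join(outdir, "tss.tsv"), sep="\t", index=False)
    tss.counts.to_csv(os.path.join(outdir, "tss_counts.tsv"),
                      sep="\t", index=False)


def write_config(config: TrioConfig, path: str) -> None:
    """Flat ``key=value`` dump of the configuration, master seed included."""
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            v = getattr(config, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"{f.name}={v}\n")
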