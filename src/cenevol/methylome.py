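"""CpG methylation calling, domain segmentation and spectrum-kernel trees.

Bisulfite pileups are turned into per-CpG binary states by a
strict-majority vote; concordance statistics restrict to sites with
coverage 2-9 to avoid collapsed repeat copies.  Runs of one state along a
chromosome are segmented into hyper-/hypomethylated regions of at least 40
CpGs.  Regions are compared by the k-spectrum kernel: with unit-norm
k-mer frequency vectors A and B and kernel K(A,B) = <A,B>, the distance is

    D(A, B) = sqrt(2 - 2 K(A, B)) = ||A - B||

(k = 8 by default).  UPGMA on this distance yields an ultrametric tree of
methylation domains, and a spectrum-kernel SVM quantifies how well
hypo- and hypermethylated sequence compositions can be told apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import encode, kmer_codes


# ---------------------------------------------------------------------------
# Calls and filtering
# ---------------------------------------------------------------------------

@dataclass
class CpGCall:
    chromosome: str
    position: int                  # 1-based, C of the CpG on the + strand
    state: str                     # "methylated" | "unmethylated"
    source: str = "bisulfite"
    methylated_count: int | None = None
    total_count: int | None = None


def call_cpg(methylated_count: int, total_count: int) -> str | None:
    """Strict-majority state call: methylated iff more than half of the
    reads support methylation, otherwise unmethylated.  No call (None)
    when there is no coverage."""
    if total_count <= 0:
        return None
    if not (0 <= methylated_count <= total_count):
        raise ValueError("methylated_count must lie in [0, total_count]")
    return "methylated" if methylated_count * 2 > total_count else "unmethylated"


def call_states(pileup: pd.DataFrame) -> pd.DataFrame:
    """Vectorized strict-majority calls for a bisulfite pileup table with
    columns chrom, pos, meth_count, total_count."""
    df = pileup[pileup["total_count"] > 0].copy()
    df["state"] = np.where(2 * df["meth_count"] > df["total_count"],
                           "methylated", "unmethylated")
    return df


def filter_for_concordance(pileup: pd.DataFrame, low: int = 2,
                           high: int = 9) -> pd.DataFrame:
    """Keep sites with coverage in [low, high] (inclusive); abnormally high
    coverage marks collapsed repeat copies and is excluded."""
    keep = (pileup["total_count"] >= low) & (pileup["total_count"] <= high)
    return pileup[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class MethylationRegion:
    chromosome: str
    start: int                     # 1-based closed
    end: int
    status: str                    # "hyper" | "hypo"
    n_cpgs: int

    @property
    def length(self) -> int:
        """Region length under the 1-based fully-closed convention."""
        return self.end - self.start + 1


def segment_regions(positions, states, chromosome="chr", min_cpgs: int = 40,
                    max_interruptions: int = 2) -> list[MethylationRegion]:
    """Maximal single-state runs along one chromosome.

    ``positions`` are sorted 1-based CpG coordinates, ``states`` a parallel
    boolean-ish array (True / "methylated" = methylated).  Each run
    tolerates up to ``max_interruptions`` opposite-state calls; runs with
    fewer than ``min_cpgs`` same-state calls are discarded.  Region bounds
    are the first and last same-state call of the run.
    """
    pos = np.asarray(positions)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    st = np.asarray([s in (True, 1, "methylated") for s in states])
    n = pos.size
    regions = []
    i = 0
    while i < n:
        s = st[i]
        last_same = i
        n_same = 1
        interruptions = 0
        j = i + 1
        while j < n:
            if st[j] == s:
                last_same = j
                n_same += 1
            else:
                if interruptions + 1 > max_interruptions:
                    break
                interruptions += 1
            j += 1
        if n_same >= min_cpgs:
            regions.append(MethylationRegion(
                chromosome=chromosome, start=int(pos[i]),
                end=int(pos[last_same]),
                status="hyper" if s else "hypo", n_cpgs=n_same))
        i = last_same + 1
    return regions


def segment_calls(calls: pd.DataFrame, **kwargs) -> list[MethylationRegion]:
    """Run :func:`segment_regions` per chromosome of a call table with
    columns chrom, pos, state (pos 1-based)."""
    out = []
    for chrom, grp in calls.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        out.extend(segment_regions(grp["pos"].to_numpy(),
                                   grp["state"].to_numpy(),
                                   chromosome=str(chrom), **kwargs))
    return out


# ---------------------------------------------------------------------------
# Concordance and ratios
# ---------------------------------------------------------------------------

def concordance(regions: list[MethylationRegion], bisulfite: pd.DataFrame):
    """Agreement of bisulfite majority calls with region-level states.

    Over filtered bisulfite CpGs falling in hypo (hyper) regions, the
    fraction called unmethylated (methylated).  Returns a dict with both
    percentages and their denominators.
    """
    called = call_states(bisulfite)
    agree = {"hypo": [0, 0], "hyper": [0, 0]}
    for reg in regions:
        sub = called[(called["chrom"].astype(str) == reg.chromosome)
                     & (called["pos"] >= reg.start)
                     & (called["pos"] <= reg.end)]
        want = "unmethylated" if reg.status == "hypo" else "methylated"
        agree[reg.status][0] += int((sub["state"] == want).sum())
        agree[reg.status][1] += len(sub)
    if agree["hypo"][1] == 0 and agree["hyper"][1] == 0:
        raise ValueError("no filtered CpGs fall inside any region")
    out = {}
    for status, (num, den) in agree.items():
        key = "pct_unmeth_agree" if status == "hypo" else "pct_meth_agree"
        out[key] = 100.0 * num / den if den else float("nan")
        out[key.replace("pct", "n")] = den
    return out


def average_methylation_ratio(n_methylated: int, n_unmethylated: int) -> float:
    """meth / (meth + unmeth), as a fraction."""
    total = n_methylated + n_unmethylated
    if total == 0:
        raise ValueError("no cytosine observations")
    return n_methylated / total


# ---------------------------------------------------------------------------
# k-mer spectra
# ---------------------------------------------------------------------------

@dataclass
class KmerSpectrum:
    k: int
    codes: np.ndarray              # sorted k-mer integer codes
    values: np.ndarray             # unit-norm frequencies, parallel to codes


def kmer_spectrum(sequence, k: int = 8) -> KmerSpectrum:
    """Euclidean-normalized k-mer frequency vector (sparse form).

    k-mers containing a non-ACGT base are skipped; a sequence with no
    valid k-mer is rejected.
    """
    arr = encode(sequence)
    codes, valid = kmer_codes(arr, k)
    codes = codes[valid]
    if codes.size == 0:
        raise ValueError(f"no valid {k}-mer in sequence")
    uniq, counts = np.unique(codes, return_counts=True)
    vals = counts.astype(float)
    vals /= np.linalg.norm(vals)
    return KmerSpectrum(k=k, codes=uniq, values=vals)


def spectrum_kernel(a: KmerSpectrum, b: KmerSpectrum) -> float:
    """Inner product of two unit-norm spectra (the k-spectrum kernel)."""
    if a.k != b.k:
        raise ValueError("spectra have different k")
    ia = np.searchsorted(a.codes, b.codes)
    ia = np.clip(ia, 0, a.codes.size - 1)
    hit = a.codes[ia] == b.codes
    return float(np.dot(a.values[ia[hit]], b.values[hit]))


def spectrum_distance(a: KmerSpectrum, b: KmerSpectrum) -> float:
    """D(A, B) = sqrt(2 - 2 K(A, B)), in [0, sqrt(2)]."""
    kab = spectrum_kernel(a, b)
    if kab >= 1.0 - 1e-12:  # identical spectra up to rounding
        return 0.0
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * kab)))


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Binary merge tree; ``merges`` rows are (node_i, node_j, height, size)
    with scipy-style node numbering (leaves 0..n-1, internal nodes n..).

    Heights follow the half-average-distance convention (an ultrametric
    node height is half the average inter-cluster distance), which differs
    by a factor of 2 from conventions that store the merge distance
    itself.
    """

    labels: list[str]
    merges: np.ndarray
    height_convention: str = "half-average-distance"

    def to_newick(self) -> str:
        n = len(self.labels)
        node_h = {i: 0.0 for i in range(n)}
        node_s = {i: self.labels[i] for i in range(n)}
        for r, (i, j, h, _size) in enumerate(self.merges):
            i, j = int(i), int(j)
            bi = h - node_h[i]
            bj = h - node_h[j]
            node_s[n + r] = f"({node_s[i]}:{bi:.6g},{node_s[j]}:{bj:.6g})"
            node_h[n + r] = h
        return node_s[n + len(self.merges) - 1] + ";"

    def leaf_root_heights(self) -> np.ndarray:
        """Height of the root above each leaf (equal iff ultrametric)."""
        root_h = float(self.merges[-1][2]) if len(self.merges) else 0.0
        return np.full(len(self.labels), root_h)

    def cut(self, k: int) -> np.ndarray:
        """Group index per leaf for a k-group cut."""
        from scipy.cluster import hierarchy as sch

        Z = self.merges.copy().astype(float)
        return sch.fcluster(Z, t=k, criterion="maxclust")


def upgma(distance: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a full distance matrix.

    Merge heights are half the inter-cluster average distance, which makes
    the tree ultrametric.  Ties are broken toward the pair with the
    smallest (minimum leaf index) labels, so the result is deterministic.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two items")
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(D < 0) \
            or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric, non-negative "
                         "with zero diagonal")
    labels = list(labels) if labels is not None else [str(i) for i in range(n)]

    active = {i: {"size": 1, "min_leaf": i, "node": i} for i in range(n)}
    dist = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_node = n
    while len(active) > 1:
        best = None
        for key, d in dist.items():
            i, j = sorted(key, key=lambda x: active[x]["min_leaf"])
            tie_key = (d, active[i]["min_leaf"], active[j]["min_leaf"])
            if best is None or tie_key < best[0]:
                best = (tie_key, i, j)
        _, i, j = best
        d = dist.pop(frozenset((i, j)))
        si, sj = active[i]["size"], active[j]["size"]
        merges.append((active[i]["node"], active[j]["node"], d / 2.0, si + sj))
        new = {"size": si + sj,
               "min_leaf": min(active[i]["min_leaf"], active[j]["min_leaf"]),
               "node": next_node}
        next_node += 1
        del active[i], active[j]
        for m in active:
            dmi = dist.pop(frozenset((m, i)))
            dmj = dist.pop(frozenset((m, j)))
            dist[frozenset((m, i))] = (si * dmi + sj * dmj) / (si + sj)
        # reuse index i for the merged cluster
        active[i] = new
        # fix the keys: entries were stored under (m, i) already
    Z = np.array([(a, b, h, s) for a, b, h, s in merges], dtype=float)
    return Dendrogram(labels=labels, merges=Z)


# ---------------------------------------------------------------------------
# Phylogeny of methylation domains
# ---------------------------------------------------------------------------

def methylation_phylogeny(regions: list[dict], k: int = 8):
    """Spectrum-kernel UPGMA tree over methylation domains.

    Each region dict needs ``sequence`` plus the label fields ``strain``,
    ``chromosome`` and ``status``; an optional boolean ``acro`` appends the
    acrocentric marker "a" to the leaf label.  Returns
    ``(Dendrogram, DataFrame of pairwise distances)``.
    """
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    labels = []
    spectra = []
    for r in regions:
        lab = f"{r['strain']}_{r['chromosome']}_{r['status']}"
        if r.get("acro"):
            lab += "_a"
        labels.append(lab)
        spectra.append(kmer_spectrum(r["sequence"], k=k))
    n = len(spectra)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = spectrum_distance(spectra[i], spectra[j])
    tree = upgma(D, labels=labels)
    table = pd.DataFrame(D, index=labels, columns=labels)
    return tree, table


# ---------------------------------------------------------------------------
# Spectrum-kernel SVM
# ---------------------------------------------------------------------------

def _windows(seqs, window: int):
    out = []
    for s in seqs:
        arr = encode(s)
        for i in range(0, arr.size - window + 1, window):
            out.append(arr[i:i + window])
    return out


def _spectrum_matrix(windows, k):
    from scipy import sparse

    rows, cols, data = [], [], []
    all_codes = {}
    for r, w in enumerate(windows):
        sp = kmer_spectrum(w, k=k)
        for c, v in zip(sp.codes, sp.values):
            cols.append(all_codes.setdefault(int(c), len(all_codes)))
            rows.append(r)
            data.append(v)
    return sparse.csr_matrix((data, (rows, cols)),
                             shape=(len(windows), len(all_codes)))


def svm_discriminate(hypo_seqs, hyper_seqs, k: int = 8, mode: str = "cv5",
                     window: int = 200, C: float = 1.0, seed: int = 0,
                     hypo_chroms=None, hyper_chroms=None):
    """Spectrum-kernel SVM separating hypo- from hypermethylated sequence.

    Sequences are cut into non-overlapping ``window``-bp sub-regions
    (short tails dropped).  ``mode="cv5"`` reports stratified five-fold
    cross-validated accuracy; ``mode="loco"`` trains on all chromosomes but
    one and tests on the held-out chromosome (requires the ``*_chroms``
    labels, one per input sequence).
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    def expand(seqs, chroms):
        wins, labs = [], []
        for idx, s in enumerate(seqs):
            arr = encode(s)
            for i in range(0, arr.size - window + 1, window):
                wins.append(arr[i:i + window])
                labs.append(chroms[idx] if chroms is not None else None)
        return wins, labs

    w0, c0 = expand(hypo_seqs, hypo_chroms)
    w1, c1 = expand(hyper_seqs, hyper_chroms)
    if not w0 or not w1:
        raise ValueError("a class has no full window; sequences shorter "
                        f"than {window} bp yield none")
    X = _spectrum_matrix(w0 + w1, k)
    y = np.array([0] * len(w0) + [1] * len(w1))
    K = (X @ X.T).toarray()

    if mode == "cv5":
        if min(len(w0), len(w1)) < 5:
            raise ValueError("cv5 needs >= 5 windows per class")
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(np.zeros(len(y)), y):
            clf = SVC(kernel="precomputed", C=C)
            clf.fit(K[np.ix_(tr, tr)], y[tr])
            accs.append(float(np.mean(clf.predict(K[np.ix_(te, tr)]) == y[te])))
        return {"mode": "cv5", "accuracy": float(np.mean(accs)),
                "fold_accuracies": accs, "n_windows": [len(w0), len(w1)],
                "seed": seed}
    if mode == "loco":
        chroms = np.array(c0 + c1)
        if any(c is None for c in chroms):
            raise ValueError("loco mode needs chromosome labels")
        per_chrom = {}
        for held in sorted(set(chroms)):
            te = chroms == held
            tr = ~te
            if len(set(y[tr])) < 2 or te.sum() == 0:
                continue
            clf = SVC(kernel="precomputed", C=C)
            tr_idx, te_idx = np.nonzero(tr)[0], np.nonzero(te)[0]
            clf.fit(K[np.ix_(tr_idx, tr_idx)], y[tr_idx])
            pred = clf.predict(K[np.ix_(te_idx, tr_idx)])
            per_chrom[str(held)] = float(np.mean(pred == y[te_idx]))
        return {"mode": "loco", "per_chromosome": per_chrom,
                "accuracy": float(np.mean(list(per_chrom.values()))),
                "n_windows": [len(w0), len(w1)]}
    raise ValueError(f"unknown mode {mode!r}")
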