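"""End-to-end pipeline: simulate a trio, run every analysis stage, report.

A :class:`RunConfig` (flat ``key=value`` file, environment overrides via
``CENEVOL_<KEY>``) selects the master seed, per-stage toggles and the trio
generator parameters.  :func:`run_all` executes the stages in dependency
order — simulation first, then repeats, methylation, Hi-C anchoring,
structural variants and TSS statistics, each independent of the others —
and collects their metrics into a :class:`Report` (JSON plus a
human-readable summary).  A stage failure is recorded and aborts only its
dependents; the report then carries a non-empty ``failures`` list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, hicanchor, methylome, repeatlib, svkit, synthio, tssins

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

STAGES = ("repeats", "methylation", "hic", "sv", "tss")


@dataclass
class RunConfig:
    """Master configuration for one pipeline run."""

    seed: int = 0
    outdir: str | None = None
    run_repeats: bool = True
    run_methylation: bool = True
    run_hic: bool = True
    run_sv: bool = True
    run_tss: bool = True
    trio: synthio.TrioConfig = field(default_factory=synthio.TrioConfig)

    def __post_init__(self):
        self.trio.seed = int(self.seed)
        self.trio.validate()

    # -- flat key=value round-trip -------------------------------------
    @classmethod
    def from_file(cls, path: str, env: dict | None = None) -> "RunConfig":
        """Load from a flat ``key=value`` file (``#`` comments allowed).

        Trio generator parameters use the ``trio.`` prefix.  Environment
        variables ``CENEVOL_<KEY>`` (dots replaced by ``_``, upper case)
        override file values.  Unknown keys are rejected.
        """
        items: dict[str, str] = {}
        with open(path) as fh:
            for ln, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value")
                k, v = line.split("=", 1)
                items[k.strip()] = v.strip()
        env = dict(os.environ if env is None else env)
        for k, v in env.items():
            if k.startswith("CENEVOL_"):
                key = k[len("CENEVOL_"):].lower()
                if key.startswith("trio_"):
                    key = "trio." + key[len("trio_"):]
                items[key] = v
        return cls.from_items(items)

    @classmethod
    def from_items(cls, items: dict) -> "RunConfig":
        own = {f.name: f for f in dataclasses.fields(cls) if f.name != "trio"}
        trio_fields = {f.name: f for f in dataclasses.fields(synthio.TrioConfig)}
        kwargs: dict = {}
        trio_kwargs: dict = {}
        for key, value in items.items():
            if key.startswith("trio."):
                name = key[len("trio."):]
                if name not in trio_fields:
                    raise ValueError(f"unknown config key: {key}")
                trio_kwargs[name] = _coerce(value, trio_fields[name].type)
            elif key in own:
                kwargs[key] = _coerce(value, own[key].type)
            else:
                raise ValueError(f"unknown config key: {key}")
        cfg = cls(**kwargs)
        for name, value in trio_kwargs.items():
            setattr(cfg.trio, name, value)
        cfg.trio.seed = cfg.seed
        cfg.trio.validate()
        return cfg

    def to_items(self) -> dict:
        items = {}
        for f in dataclasses.fields(self):
            if f.name == "trio":
                continue
            v = getattr(self, f.name)
            if v is not None:
                items[f.name] = v
        for f in dataclasses.fields(synthio.TrioConfig):
            v = getattr(self.trio, f.name)
            if v is not None:
                items[f"trio.{f.name}"] = v
        return items

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.to_items().items()):
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{k}={v}\n")

    def config_hash(self) -> str:
        blob = json.dumps({k: list(v) if isinstance(v, tuple) else v
                           for k, v in sorted(self.to_items().items())},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _coerce(value, annotation):
    if not isinstance(value, str):
        return value
    ann = str(annotation)
    if "bool" in ann:
        if value.lower() in ("1", "true", "yes", "on"):
            return True
        if value.lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {value!r}")
    if "tuple" in ann:
        parts = [p for p in value.replace("(", "").replace(")", "").split(",")
                 if p.strip()]
        return tuple(int(float(p)) for p in parts)
    if "int" in ann:
        return int(value)
    if "float" in ann:
        return float(value)
    return value


@dataclass
class Report:
    """Structured result of one :func:`run_all` invocation."""

    seed: int
    config_hash: str
    version: str = __version__
    schema_version: int = REPORT_SCHEMA_VERSION
    stages: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    runtime_s: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2,
                          default=_jsonable, sort_keys=True)

    def summary(self) -> str:
        lines = [f"cenevol {self.version} report (seed={self.seed}, "
                 f"config={self.config_hash})"]
        for stage in ("simulate",) + STAGES:
            if stage not in self.stages:
                lines.append(f"  {stage}: skipped")
                continue
            m = self.stages[stage]
            if isinstance(m, dict):
                keys = ", ".join(f"{k}={_short(v)}" for k, v in sorted(m.items())
                                 if np.isscalar(v) or v is None)
                lines.append(f"  {stage}: {keys}")
        for f in self.failures:
            lines.append(f"  FAILED {f['stage']}: {f['error']}")
        return "\n".join(lines) + "\n"


def _short(v):
    if isinstance(v, float):
        return f"{v:.4g}"
    return v


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    return str(o)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_repeats(trio: synthio.Trio) -> dict:
    truth = trio.truth
    strain = "ing1"
    mlen = trio.config.monomer_length
    clusters_by_chrom: dict = {}
    sequences: dict = {}
    classes: dict = {}
    for cen in truth.centromeres:
        c = cen.chrom
        iv = truth.centromere_interval(strain, c)
        region_seq = trio.sequence(strain, c)[iv[0]:iv[1]]
        region = repeatlib.CentromereRegion(
            strain=strain, chromosome=str(c), start=iv[0] + 1, end=iv[1],
            positional_class=("acro" if cen.clazz == "acro" else "nonacro"))
        monomers = repeatlib.monomers_from_region(
            region, region_seq, template=region_seq[:mlen])
        clusters = repeatlib.cluster_monomers(monomers)
        clusters_by_chrom[str(c)] = clusters
        sequences.update({m.id: m.sequence for m in monomers})
        classes[str(c)] = region.positional_class
    records = repeatlib.best_match_associations(clusters_by_chrom, sequences,
                                               classes)
    comp = repeatlib.compare_similarity_groups(records)
    return {
        "n_chromosomes": len(clusters_by_chrom),
        "n_associations": len(records),
        "medians": comp["medians"],
        "p_values": comp["p_values"],
        "summary_table": comp["summary"],
    }


def _stage_methylation(trio: synthio.Trio) -> dict:
    tracks = synthio.generate_methylation(trio)
    truth = trio.truth
    strain_regions = {}
    region_dicts = []
    for strain in synthio.STRAINS:
        calls = tracks.calls[strain].copy()
        calls["pos"] = calls["pos"] + 1          # 0-based track -> 1-based
        regions = methylome.segment_calls(calls)
        strain_regions[strain] = regions
        for r in regions:
            if r.status != "hypo":
                continue
            cen = truth.centromere_interval(strain, int(r.chromosome))
            if cen is None or not (cen[0] < r.start and r.end <= cen[1]):
                continue
            seq = trio.sequence(strain, int(r.chromosome))[r.start - 1:r.end]
            region_dicts.append({
                "sequence": seq, "strain": strain,
                "chromosome": str(int(r.chromosome) + 1),
                "status": "hypo",
                "acro": truth.classes[int(r.chromosome)] == "acro"})
    n_hypo = len(region_dicts)
    out = {"n_hypo_domains_in_arrays": n_hypo,
           "n_planted_domains": len(truth.hypo_domains) * len(synthio.STRAINS)}
    if n_hypo >= 4:
        tree, dist = methylome.methylation_phylogeny(region_dicts)
        out["newick"] = tree.to_newick()
        out["n_leaves"] = len(tree.labels)
    return out


def _stage_hic(trio: synthio.Trio) -> dict:
    hic = synthio.generate_hic_contacts(trio)
    truth = trio.truth
    vecs, labels, lengths = [], [], []
    for ct in truth.contigs:
        row = hic.contacts.loc[ct.contig]
        vecs.append(hicanchor.ContactVector(contig=ct.contig,
                                            counts=row.to_numpy(float)))
        labels.append(f"chr{ct.chrom + 1}")
        lengths.append(ct.end - ct.start)
    chromosomes = list(hic.contacts.columns)
    correct = 0
    for i in range(len(vecs)):
        model = hicanchor.fit_nb(
            [v for j, v in enumerate(vecs) if j != i],
            [l for j, l in enumerate(labels) if j != i],
            chromosomes,
            {v.contig: lg for j, (v, lg) in enumerate(zip(vecs, lengths))
             if j != i})
        _, pred = hicanchor.classify_orphan(model, vecs[i])
        correct += int(pred == labels[i])
    return {"n_contigs": len(vecs),
            "leave_one_out_accuracy": correct / len(vecs)}


def _stage_sv(trio: synthio.Trio) -> dict:
    events = []
    for c in sorted(trio.genomes["ing1"]):
        evs = svkit.compare_pair_with_outgroup(
            trio.sequence("ing1", c), trio.sequence("ing2", c),
            trio.sequence("out", c), chrom=str(c),
            strain_a="ing1", strain_b="ing2")
        events += evs
    bal = svkit.indel_balance_summary(events)
    return {"n_events": len(events),
            "n_insertions": bal["n_insertions"],
            "n_deletions": bal["n_deletions"],
            "insertion_deletion_ratio": bal["insertion_deletion_ratio"],
            "balance_table": bal["table"],
            "events": svkit.events_to_frame(events)}


def _stage_tss(trio: synthio.Trio) -> dict:
    tssd = synthio.generate_tss_counts(trio)
    tracks = synthio.generate_methylation(trio)
    ins = synthio.tss_insertion_events(trio)
    with_ins, partners = tssins.find_insertion_tss_pairs(tssd.table, ins)
    out: dict = {"n_pairs": len(with_ins)}
    if len(with_ins) >= 6:
        ws_with, ws_without = [], []
        for w, p in zip(with_ins, partners):
            for rec, dest in ((w.tss, ws_with), (p, ws_without)):
                chrom = int(rec.chromosome)
                lk = tssins.calls_to_lookup(tracks.calls[rec.strain],
                                            chrom=chrom)
                dest.append(tssins.window_stats(
                    trio.sequence(rec.strain, chrom), rec, methylation=lk))
        tests = tssins.paired_increase_tests(ws_with, ws_without)
        out["paired_tests"] = tests
        for _, r in tests.iterrows():
            out[f"p_{r['parameter']}"] = r["p_value"]
    scr = tssins.expression_screen(tssd.counts, "ing1", "ing2")
    out["n_tss"] = len(scr)
    out["n_significant_expression"] = int((scr["p_value"] < 0.01).sum())
    out["n_novel"] = int(scr["novel"].sum())
    out["expression_table"] = scr
    return out


_STAGE_FUNCS = {"repeats": _stage_repeats, "methylation": _stage_methylation,
                "hic": _stage_hic, "sv": _stage_sv, "tss": _stage_tss}


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> Report:
    """Run the enabled stages and collect a report.

    The simulation stage runs first and every analysis stage depends only
    on it, so disabling one stage leaves the others untouched.  Stage
    exceptions are caught, logged and recorded in ``report.failures``.
    """
    report = Report(seed=config.seed, config_hash=config.config_hash())
    t0 = time.time()
    try:
        log.info("[simulate] generating trio (seed=%d)", config.seed)
        trio = synthio.generate_trio(config.trio)
        needs_arrays = config.run_repeats or config.run_methylation
        if needs_arrays:
            trio = synthio.generate_centromere_arrays(trio)
        report.stages["simulate"] = {
            "n_chromosomes": config.trio.n_chromosomes,
            "n_planted_svs": len(trio.truth.svs),
            "n_planted_tss": len(trio.truth.tss)}
    except Exception as exc:                     # noqa: BLE001
        log.exception("[simulate] failed")
        report.failures.append({"stage": "simulate", "error": str(exc)})
        return report
    finally:
        report.runtime_s["simulate"] = round(time.time() - t0, 3)

    for stage in STAGES:
        if not getattr(config, f"run_{stage}"):
            log.info("[%s] disabled", stage)
            continue
        t0 = time.time()
        try:
            log.info("[%s] running", stage)
            report.stages[stage] = _STAGE_FUNCS[stage](trio)
        except Exception as exc:                 # noqa: BLE001
            log.exception("[%s] failed", stage)
            report.failures.append({"stage": stage, "error": str(exc)})
        finally:
            report.runtime_s[stage] = round(time.time() - t0, 3)

    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        with open(os.path.join(config.outdir, "report.json"), "w") as fh:
            fh.write(report.to_json())
        with open(os.path.join(config.outdir, "summary.txt"), "w") as fh:
            fh.write(report.summary())
        config.to_file(os.path.join(config.outdir, "run.cfg"))
        log.info("report written to %s", config.outdir)
    return report
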