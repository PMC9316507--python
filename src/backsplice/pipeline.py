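"""End-to-end pipeline: simulate/load -> annotate -> confirm -> dedupe ->
features -> report.

The pipeline is driven by a single YAML (or dict) configuration:

.. code-block:: yaml

    seed: 1
    simulation:            # either this block ...
      n_circrnas: 5
      reads_per_circ: 3
      n_exons: 10          # plus any generator field (read_length, ...)
    model:                 # ... or an explicit gene model
      bed: exons.bed
      fasta: gene.fa
    reads: reads.fa        # required when no simulation block
    annotate:              # optional annotator overrides (min_anchor, ...)
      min_anchor: 18
    primers:               # optional: design divergent pairs per exon
      exons: [6]
    features:              # optional feature scans on the catalog
      mirnas: mirnas.fa
      rbp_motifs: motifs.tsv
    output: outdir

Every stage logs its in/out counts; outputs are a catalog TSV, per-read
annotation JSON, a rejected-reads log, primer and feature tables, and a
summary JSON.  An empty confirmed set raises :class:`PipelineError`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from .gene_model import GeneModel, load_gene_model
from .annotate import AnnotateParams, annotate_read, dedupe_and_catalog
from .simulate import SimConfig, simulate_gene, simulate_circrna, simulate_reads, write_reads_fasta
from .primers import PrimerConstraints, design_divergent_pair, design_second_round
from .features import find_orfs, scan_m6a, scan_mirna_sites, scan_rbp_motifs
from .report import summarize_catalog, write_catalog

__all__ = ["PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("backsplice")


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path} is not a mapping")
    return cfg


def _require(cfg: dict, key: str) -> object:
    if key not in cfg:
        raise PipelineError(f"missing required config key: {key!r}")
    return cfg[key]


def _sim_config(cfg: dict, seed: int) -> SimConfig:
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    kwargs = {k: tuple(v) if isinstance(v, list) else v
              for k, v in cfg.items() if k in fields}
    return SimConfig(seed=seed, **kwargs)


def _annotate_params(cfg: dict) -> AnnotateParams:
    fields = {f.name for f in dataclasses.fields(AnnotateParams)}
    return AnnotateParams(**{k: v for k, v in cfg.items() if k in fields})


def run_pipeline(config: dict | str | Path, out_dir: Optional[str | Path] = None) -> dict:
    """Run the full dry-lab workflow described by ``config``.

    Returns a dict of artifact paths plus the in-memory catalog.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("output", "backsplice_out"))
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # ---- stage 1: obtain model and reads -------------------------------
    if "simulation" in config:
        sim_cfg = _sim_config(config["simulation"], seed)
        n_circ = int(config["simulation"].get("n_circrnas", 5))
        reads_per = int(config["simulation"].get("reads_per_circ", 3))
        model = simulate_gene(sim_cfg)
        rng = sim_cfg.rng()
        circles, reads, read_samples = [], [], []
        for i in range(n_circ):
            circ, truth = simulate_circrna(
                model, sim_cfg, rng=rng, circ_id=f"truth-{i + 1}", plant=False
            )
            circles.append((circ, truth))
            for read in simulate_reads(circ, reads_per, sim_cfg, rng=rng):
                reads.append(read)
                read_samples.append("simulated")
        model.write_bed_fasta(out / "gene.bed", out / "gene.fa")
        model.write_json(out / "gene_model.json")
        write_reads_fasta(reads, out / "reads.fa")
        with open(out / "truth.json", "w") as fh:
            fh.write("[\n" + ",\n".join(t.to_json() for _, t in circles) + "\n]\n")
        read_seqs = [(r.id, r.sequence) for r in reads]
        log.info("simulate: %d circles, %d reads", n_circ, len(reads))
        artifacts["model"] = str(out / "gene_model.json")
        artifacts["reads"] = str(out / "reads.fa")
    else:
        model_cfg = _require(config, "model")
        model = load_gene_model(_require(model_cfg, "bed"), _require(model_cfg, "fasta"))
        reads_path = _require(config, "reads")
        read_seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(reads_path), "fasta")]
        read_samples = ["input"] * len(read_seqs)
        log.info("load: model %s (%d exons), %d reads",
                 model.gene_id, model.n_exons, len(read_seqs))

    # ---- stage 2: annotate + confirm -----------------------------------
    params = _annotate_params(config.get("annotate", {}))
    results = [annotate_read(seq, model, read_id=rid, params=params)
               for rid, seq in read_seqs]
    confirmed = [r for r in results if r.confirmed]
    rejected = [r for r in results if not r.confirmed]
    log.info("annotate: %d reads in, %d confirmed, %d rejected",
             len(results), len(confirmed), len(rejected))
    ann_doc = [
        {
            "read_id": r.read_id,
            "confirmed": r.confirmed,
            "rejection_reason": r.rejection_reason,
            "collapsed_period": r.collapsed_period,
            "exons": r.circ.exon_indices if r.circ else None,
            "length_nt": r.circ.length if r.circ else None,
            "ambiguity_k": r.bsj.ambiguity_k if r.bsj else None,
        }
        for r in results
    ]
    (out / "annotations.json").write_text(json.dumps(ann_doc, indent=1, sort_keys=True) + "\n")
    (out / "rejected.log").write_text(
        "".join(f"{r.read_id}\t{r.rejection_reason}\n" for r in rejected)
    )
    artifacts["annotations"] = str(out / "annotations.json")

    # ---- stage 3: dedupe + catalog --------------------------------------
    samples = [read_samples[i] for i, r in enumerate(results) if r.confirmed]
    catalog = dedupe_and_catalog([r.circ for r in confirmed], samples=samples)
    write_catalog(catalog.table, out / "catalog.tsv")
    log.info("catalog: %d confirmed reads -> %d distinct circRNAs",
             len(confirmed), len(catalog))
    artifacts["catalog"] = str(out / "catalog.tsv")

    # ---- stage 4: primers (optional) ------------------------------------
    if "primers" in config:
        rows = []
        constraints_cfg = config.get("primer_constraints", {})
        constraints = PrimerConstraints(
            **{k: tuple(v) for k, v in constraints_cfg.items()
               if k in ("length", "gc", "tm")}
        )
        for exon_index in config["primers"].get("exons", []):
            pair = design_divergent_pair(model, int(exon_index), constraints)
            inner = design_second_round(pair, model, mode="nested", constraints=constraints)
            for p in (pair, inner):
                rows.append({
                    "name": f"exon{p.target_exon_index}_{p.round}",
                    "round": p.round,
                    "exon": p.target_exon_index,
                    "forward": p.forward, "reverse": p.reverse,
                    "fwd_start": p.forward_start, "fwd_end": p.forward_end,
                    "rev_start": p.reverse_start, "rev_end": p.reverse_end,
                    "tm_fwd": round(p.tm_forward, 2), "tm_rev": round(p.tm_reverse, 2),
                    "gc_fwd": round(p.gc_forward, 3), "gc_rev": round(p.gc_reverse, 3),
                })
        pd.DataFrame(rows).to_csv(out / "primers.tsv", sep="\t", index=False)
        log.info("primers: %d pairs designed", len(rows))
        artifacts["primers"] = str(out / "primers.tsv")

    # ---- stage 5: features ----------------------------------------------
    feat_cfg = config.get("features", {})
    features_doc = {}
    for circ in catalog.circrnas:
        entry = {
            "length_nt": circ.length,
            "orfs": [dataclasses.asdict(o) for o in find_orfs(circ, "circular")],
            "m6a_sites": [dataclasses.asdict(s) for s in scan_m6a(circ)],
        }
        if "mirnas" in feat_cfg:
            entry["mirna_sites"] = [
                dataclasses.asdict(s) for s in scan_mirna_sites(circ, feat_cfg["mirnas"])
            ]
        if "rbp_motifs" in feat_cfg:
            motifs = pd.read_csv(feat_cfg["rbp_motifs"], sep="\t")
            table = dict(zip(motifs.iloc[:, 0], motifs.iloc[:, 1]))
            entry["rbp_counts"] = [
                {k: v for k, v in dataclasses.asdict(c).items() if k != "positions"}
                for c in scan_rbp_motifs(circ, table)
            ]
        features_doc[circ.id] = entry
    (out / "features.json").write_text(
        json.dumps(features_doc, indent=1, sort_keys=True) + "\n"
    )
    artifacts["features"] = str(out / "features.json")

    # ---- stage 6: summary ------------------------------------------------
    if len(catalog) == 0:
        raise PipelineError(
            "no circRNA confirmed: no read contained the back-splice junction "
            f"(see {out / 'rejected.log'})"
        )
    summary = summarize_catalog(catalog.table)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    artifacts["summary"] = str(out / "summary.json")
    artifacts["catalog_df"] = catalog.table
    artifacts["n_confirmed_reads"] = len(confirmed)
    return artifacts
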