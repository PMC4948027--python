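"""Pipeline orchestration: run every configured stage from one config.

The config is a plain YAML mapping with three top-level keys::

    seed: 1                 # recorded in the manifest
    outdir: results/        # created if absent
    inputs:                 # stages run iff their inputs are present
      protein_fasta: proteins.fa          # -> profile stage
      domain_coords: coords.tsv           # -> domains stage (with protein_fasta)
      pair_manifest: pairs.tsv            # -> kaks stage (pair_id, fasta columns)
      locus_tsv: loci.tsv                 # -> dupscan (with homologs)
      gff: genes.gff3                     # alternative to locus_tsv
      homologs: homologs.tsv
      promoter_fasta: promoters.fa        # -> promscan stage
      catalog: catalog.json               # optional, defaults to packaged
      ct_tsv: qpcr.tsv                    # -> express stage
      design: treatment                   # or "tissue"
    params:                 # optional overrides, all echoed in the manifest
      synteny_window: 15
      min_anchors: 3
      tandem_max_intervening: 5
      kaks_window_bp: 90
      kaks_step_bp: 9
      lambda_rate: 9.1e-9
      nls_min_basic: 4
      nls_window: 8

Unknown keys anywhere are rejected. Every parameter in force is echoed
into ``manifest.json`` together with SHA-256 checksums of all inputs, so
a rerun with the same config and inputs is byte-identical and the
manifest changes iff inputs or parameters change. A failing stage raises
:class:`~genefam.errors.StageError` naming the stage; outputs of earlier
stages are left in place.
"""
from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .errors import StageError, ValidationError
from . import io as gio
from . import seqprops, domains, molevol, genomevol, promoters, expression

log = logging.getLogger("genefam")

DEFAULT_PARAMS: dict = {
    "synteny_window": 15,
    "min_anchors": 3,
    "tandem_max_intervening": 5,
    "kaks_window_bp": 90,
    "kaks_step_bp": 9,
    "lambda_rate": molevol.POPULUS_LAMBDA,
    "nls_min_basic": 4,
    "nls_window": 8,
}

KNOWN_INPUTS = {
    "protein_fasta", "domain_coords", "pair_manifest", "locus_tsv", "gff",
    "homologs", "promoter_fasta", "catalog", "ct_tsv", "design", "paralogs",
}
KNOWN_TOP = {"seed", "outdir", "inputs", "params", "log_level"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = Path(path).parent
    inputs = cfg.get("inputs") or {}
    for key, val in inputs.items():
        if key == "design":
            continue
        p = Path(val)
        if not p.is_absolute():
            inputs[key] = str(base / p)
    return cfg


def _validate_config(cfg: Mapping) -> tuple[dict, dict]:
    unknown = set(cfg) - KNOWN_TOP
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    inputs = dict(cfg.get("inputs") or {})
    unknown = set(inputs) - KNOWN_INPUTS
    if unknown:
        raise ValidationError(f"unknown input keys: {sorted(unknown)}")
    params = dict(DEFAULT_PARAMS)
    overrides = dict(cfg.get("params") or {})
    unknown = set(overrides) - set(DEFAULT_PARAMS)
    if unknown:
        raise ValidationError(f"unknown param keys: {sorted(unknown)}")
    params.update(overrides)
    for key, val in inputs.items():
        if key != "design" and not os.path.exists(val):
            raise ValidationError(f"input file missing: {key}={val}")
    return inputs, params


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ValidationError, StageError):
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
                raise StageError(name, str(exc)) from exc
        wrapped.__name__ = fn.__name__
        return wrapped
    return deco


@_stage("profile")
def _run_profile(inputs, params, outdir: Path) -> dict:
    records = gio.read_protein_fasta(inputs["protein_fasta"])
    table = seqprops.profile_table(records)
    out = outdir / "profile.tsv"
    table.to_csv(out, sep="\t", index=False)
    return {"profile": str(out)}


@_stage("domains")
def _run_domains(inputs, params, outdir: Path) -> dict:
    seqs = gio.read_fasta(inputs["protein_fasta"])
    coords = pd.read_csv(inputs["domain_coords"], sep="\t")
    span_rows, class_rows = [], []
    for gid, seq in seqs.items():
        for sp in domains.scan_protein(
            seq, nls_min_basic=params["nls_min_basic"], nls_window=params["nls_window"]
        ):
            span_rows.append(
                {"id": gid, "kind": sp.kind, "start": sp.start, "end": sp.end,
                 "matched_text": sp.matched_text}
            )
        rows = coords[coords["id"] == gid]
        kinds = {r.kind: (int(r.start), int(r.end)) for r in rows.itertuples()}
        if "DBD" in kinds and "HR-A/B" in kinds:
            dbd = domains.DomainSpan(
                "DBD", *kinds["DBD"], seq[kinds["DBD"][0] - 1 : kinds["DBD"][1]]
            )
            hr = domains.DomainSpan(
                "HR-A/B", *kinds["HR-A/B"],
                seq[kinds["HR-A/B"][0] - 1 : kinds["HR-A/B"][1]],
            )
            cls = domains.classify_hsf(dbd, hr)
            class_rows.append(
                {"id": gid, "hsf_class": cls.hsf_class, "linker_len": cls.linker_len,
                 "hr_span_len": cls.hr_span_len, "rationale": cls.rationale}
            )
    spans_out = outdir / "domain_spans.tsv"
    classes_out = outdir / "hsf_classes.tsv"
    pd.DataFrame(span_rows).to_csv(spans_out, sep="\t", index=False)
    pd.DataFrame(class_rows).to_csv(classes_out, sep="\t", index=False)
    return {"domain_spans": str(spans_out), "hsf_classes": str(classes_out)}


@_stage("kaks")
def _run_kaks(inputs, params, outdir: Path) -> dict:
    manifest = pd.read_csv(inputs["pair_manifest"], sep="\t")
    if not {"pair_id", "fasta"} <= set(manifest.columns):
        raise ValidationError("pair manifest needs columns: pair_id, fasta")
    base = Path(inputs["pair_manifest"]).parent
    rows = []
    window_rows = []
    for r in manifest.itertuples():
        fasta = Path(r.fasta)
        if not fasta.is_absolute():
            fasta = base / fasta
        pair = gio.read_pair_fasta(fasta)
        res = molevol.kaks_ng86(pair)
        t = molevol.divergence_time(res.Ks, params["lambda_rate"])
        rows.append(
            {"pair_id": r.pair_id, "id_a": pair.id_a, "id_b": pair.id_b,
             "Ka": round(res.Ka, 4), "Ks": round(res.Ks, 4),
             "KaKs": res.ratio_str, "S": round(res.S, 2), "N": round(res.N, 2),
             "Sd": round(res.Sd, 2), "Nd": round(res.Nd, 2),
             "T_MYA": round(t.t_mya, 2)}
        )
        if params["kaks_window_bp"] <= len(pair.seq_a):
            prof = molevol.sliding_window_kaks(
                pair, params["kaks_window_bp"], params["kaks_step_bp"]
            )
            for w in prof.windows:
                window_rows.append(
                    {"pair_id": r.pair_id, "start": w.start_bp, "end": w.end_bp,
                     "Ka": "NA" if w.Ka is None else round(w.Ka, 4),
                     "Ks": "NA" if w.Ks is None else round(w.Ks, 4),
                     "KaKs": "NA" if w.ratio is None else round(w.ratio, 4),
                     "flag": w.flag}
                )
    kaks_out = outdir / "kaks.tsv"
    pd.DataFrame(rows).to_csv(kaks_out, sep="\t", index=False)
    outputs = {"kaks": str(kaks_out)}
    if window_rows:
        win_out = outdir / "kaks_windows.tsv"
        header = (
            f"# window_bp={params['kaks_window_bp']} step_bp={params['kaks_step_bp']}\n"
        )
        with open(win_out, "w") as fh:
            fh.write(header)
            pd.DataFrame(window_rows).to_csv(fh, sep="\t", index=False)
        outputs["kaks_windows"] = str(win_out)
    return outputs


@_stage("dupscan")
def _run_dupscan(inputs, params, outdir: Path) -> dict:
    if "locus_tsv" in inputs:
        loci = gio.read_locus_tsv(inputs["locus_tsv"])
    else:
        loci = gio.read_gff3_loci(inputs["gff"])
    homologs = gio.read_homolog_tsv(inputs["homologs"])
    blocks = genomevol.find_duplicated_blocks(
        loci, homologs, params["synteny_window"], params["min_anchors"]
    )
    block_rows = [
        {"block_id": i, "scaffold_a": b.scaffold_a, "scaffold_b": b.scaffold_b,
         "n_anchors": len(b.anchors),
         "anchors": ";".join(f"{a}|{bb}" for a, bb in b.anchors)}
        for i, b in enumerate(blocks)
    ]
    call_rows = []
    for ga, gb in homologs:
        call = genomevol.classify_duplication(
            (ga, gb), blocks, loci,
            params["tandem_max_intervening"], params["synteny_window"],
        )
        call_rows.append(
            {"gene_a": ga, "gene_b": gb, "dup_type": call.dup_type,
             "evidence": call.evidence}
        )
    blocks_out = outdir / "synteny_blocks.tsv"
    calls_out = outdir / "duplication_calls.tsv"
    pd.DataFrame(block_rows).to_csv(blocks_out, sep="\t", index=False)
    pd.DataFrame(call_rows).to_csv(calls_out, sep="\t", index=False)
    return {"synteny_blocks": str(blocks_out), "duplication_calls": str(calls_out)}


@_stage("promscan")
def _run_promscan(inputs, params, outdir: Path) -> dict:
    seqs = gio.read_fasta(inputs["promoter_fasta"])
    catalog = (
        promoters.CisElementCatalog.from_file(inputs["catalog"])
        if "catalog" in inputs
        else promoters.CisElementCatalog.default()
    )
    proms = [promoters.PromoterSequence(g, s) for g, s in seqs.items()]
    hits = promoters.scan_promoters(proms, catalog)
    hits_out = outdir / "element_hits.tsv"
    pd.DataFrame(
        [
            {"gene_id": h.gene_id, "element": h.element_name, "start": h.start,
             "strand": h.strand, "matched_text": h.matched_text}
            for h in hits
        ],
        columns=["gene_id", "element", "start", "strand", "matched_text"],
    ).to_csv(hits_out, sep="\t", index=False)
    summary = promoters.enrichment_table(
        promoters.summarize_enrichment(hits, catalog)
    )
    summary_out = outdir / "element_enrichment.tsv"
    summary.to_csv(summary_out, sep="\t", index=False)
    return {"element_hits": str(hits_out), "element_enrichment": str(summary_out)}


@_stage("express")
def _run_express(inputs, params, outdir: Path) -> dict:
    table = gio.read_ct_tsv(inputs["ct_tsv"])
    design = inputs.get("design", "treatment")
    outputs = {}
    if design == "treatment":
        calls = expression.call_inductions(table)
        calls_out = outdir / "induction_calls.tsv"
        calls.to_csv(calls_out, sep="\t", index=False)
        counts = expression.count_induced_per_condition(calls)
        counts_out = outdir / "induced_counts.tsv"
        counts.to_csv(counts_out, sep="\t", index=False)
        matrix = calls.pivot_table(
            index="gene_id", columns=["condition", "timepoint_h"], values="log2fc"
        )
        matrix_out = outdir / "log2fc_matrix.tsv"
        matrix.to_csv(matrix_out, sep="\t")
        outputs = {
            "induction_calls": str(calls_out),
            "induced_counts": str(counts_out),
            "log2fc_matrix": str(matrix_out),
        }
    elif design == "tissue":
        profile = expression.tissue_profile_table(table)
        out = outdir / "tissue_profiles.tsv"
        profile.to_csv(out, sep="\t")
        outputs = {"tissue_profiles": str(out)}
    else:
        raise ValidationError(f"unknown design {design!r}")
    return outputs


STAGES = [
    ("profile", _run_profile, {"protein_fasta"}),
    ("domains", _run_domains, {"protein_fasta", "domain_coords"}),
    ("kaks", _run_kaks, {"pair_manifest"}),
    ("dupscan", _run_dupscan, {"homologs"}),
    ("promscan", _run_promscan, {"promoter_fasta"}),
    ("express", _run_express, {"ct_tsv"}),
]


def run_pipeline(config, outdir: Optional[str] = None) -> dict:
    """Run all configured stages; returns {stage: {output_name: path}}."""
    cfg = load_config(config) if not isinstance(config, Mapping) else dict(config)
    inputs, params = _validate_config(cfg)
    if "dupscan" in [s for s, _, need in STAGES if need <= set(inputs)]:
        if "locus_tsv" not in inputs and "gff" not in inputs:
            raise ValidationError("dupscan needs locus_tsv or gff alongside homologs")
    out = Path(outdir or cfg.get("outdir") or "genefam_out")
    out.mkdir(parents=True, exist_ok=True)

    resolved = {
        "seed": cfg.get("seed"),
        "outdir": str(out),
        "inputs": inputs,
        "params": params,
    }
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)

    results = {}
    for name, fn, needed in STAGES:
        if not needed <= set(inputs):
            continue
        log.info("running stage %s", name)
        results[name] = fn(inputs, params, out)

    manifest = {
        "genefam_version": __version__,
        "seed": cfg.get("seed"),
        "params": {k: params[k] for k in sorted(params)},
        "inputs": {
            k: (v if k == "design" else {"path": v, "sha256": gio.sha256_file(v)})
            for k, v in sorted(inputs.items())
        },
        "stages": {k: sorted(v) for k, v in results.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = {"manifest": str(out / "manifest.json")}
    return results
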