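"""End-to-end orchestration: network -> classification -> models -> centrality.

A single :class:`RunConfig` drives the whole analysis.  Inputs are either
synthetic (a :class:`~rbpregulon.synth.GeneratorConfig` under ``synth``)
or paths to real files.  Every run writes a machine-readable manifest with
the config hash and a SHA-256 per output, which also powers coarse
resumption: a completed run whose manifest matches the config verbatim is
not recomputed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .centrality import centralities, compare_groups, sync_partition
from .classify import run_level
from .features import (
    RBP_PREDICTORS,
    biotype_effect_summary,
    fit_elastic_net,
    fit_multivariate,
    fit_stepwise,
    per_rbp_transcript_models,
    rbp_feature_table,
    transcript_feature_table,
)
from .formats import (
    read_annotation,
    read_edge_list,
    read_expression,
    read_peaks,
    write_classification,
    write_feature_table,
    write_network,
)
from .network import map_targets, network_summary
from .synth import GeneratorConfig, generate, write_fixtures

__all__ = ["RunConfig", "InputPaths", "run_all"]


class InputPaths(BaseModel):
    gtf: str
    peaks: list[str]  # one BED per RBP; rbp_id = file stem
    expr_rna: str
    expr_protein: str | None = None
    ppi: str | None = None
    domains: str | None = None
    p_value_column: int = 4
    log10_p: bool = False


class RunConfig(BaseModel):
    """Full pipeline configuration with the study's default thresholds."""

    seed: int = 0
    flank: int = 300
    alpha: float = 0.05
    n_reps: int = 100
    respect_strand: bool = False
    exclude_self: bool = False
    synth: GeneratorConfig | None = None
    inputs: InputPaths | None = None

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, outdir: str | Path, resume: bool = True) -> dict:
    """Run every stage; returns the manifest (also written as JSON).

    With ``resume=True`` a previous completed run in ``outdir`` whose
    manifest matches this config (and whose outputs still hash correctly)
    is returned as-is.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == config.config_hash() and all(
            Path(o["path"]).exists() and _sha256(Path(o["path"])) == o["sha256"]
            for o in prev.get("outputs", {}).values()
        ):
            return prev

    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
        "warnings": [],
    }

    def register(name: str, path: Path, n_rows: int | None = None) -> None:
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
            **({"n_rows": n_rows} if n_rows is not None else {}),
        }

    # --- stage 0: inputs -------------------------------------------------
    if config.synth is not None:
        data = generate(config.synth)
        fixture_paths = write_fixtures(data, outdir / "fixtures")
        annotation = data.annotation
        peaks = data.peaks
        expr_rna, expr_protein = data.expr_rna, data.expr_protein
        ppi_edges = data.ppi_edges
        domain_counts = data.domain_counts
        rbp_genes = data.truth.rbp_genes
        for name, p in fixture_paths.items():
            register(f"fixtures/{name}", p)
        manifest["stages"]["synth"] = {"n_transcripts": len(annotation), "n_peaks": len(peaks)}
    elif config.inputs is not None:
        ip = config.inputs
        annotation = read_annotation(ip.gtf)
        peaks = []
        for bed in ip.peaks:
            peaks.extend(
                read_peaks(bed, p_value_column=ip.p_value_column, log10_p=ip.log10_p)
            )
        expr_rna = read_expression(ip.expr_rna, level="transcript")
        expr_protein = (
            read_expression(ip.expr_protein, level="protein")
            if ip.expr_protein
            else None
        )
        ppi_edges = read_edge_list(ip.ppi) if ip.ppi else []
        domain_counts = {}
        if ip.domains:
            dom = pd.read_csv(ip.domains, sep="\t")
            domain_counts = dict(zip(dom.iloc[:, 0].astype(str), dom.iloc[:, 1]))
        rbp_ids = {p.rbp_id for p in peaks}
        rbp_genes = {r: r for r in rbp_ids}  # rbp id doubles as gene id
    else:
        raise ValueError("config needs either 'synth' or 'inputs'")

    # --- stage 1: network -----------------------------------------------
    exclude = rbp_genes if config.exclude_self else None
    net = map_targets(
        peaks,
        annotation,
        flank=config.flank,
        respect_strand=config.respect_strand,
        exclude_self=exclude,
    )
    net_path = outdir / "network.tsv"
    write_network(net, net_path)
    summary_table, union = network_summary(net)
    summary_table.to_csv(outdir / "network_summary.tsv", sep="\t", index=False)
    register("network", net_path, sum(len(t) for t in net.targets.values()))
    register("network_summary", outdir / "network_summary.tsv")
    manifest["stages"]["network"] = {
        "n_rbps": len(net.targets),
        "union_targets": union,
    }

    # --- stage 2: classification ----------------------------------------
    records_by_level = {}
    for level in ("transcript", "protein"):
        if level == "protein" and (
            expr_protein is None or len(expr_protein.data) == 0
        ):
            manifest["warnings"].append(
                "no protein expression matrix; protein-level classification skipped"
            )
            continue
        records, summary = run_level(
            rbp_genes,
            net,
            expr_rna,
            annotation,
            expr_protein=expr_protein,
            level=level,
            alpha=config.alpha,
            n_reps=config.n_reps,
            seed=config.seed,
        )
        records_by_level[level] = records
        cls_path = outdir / f"classification_{level}.tsv"
        write_classification(records, cls_path)
        register(f"classification_{level}", cls_path, len(records))
        long_df = pd.concat([r.long_rows() for r in records], ignore_index=True)
        long_path = outdir / f"rho_long_{level}.tsv"
        long_df.to_csv(long_path, sep="\t", index=False, float_format="%.6g")
        register(f"rho_long_{level}", long_path, len(long_df))
        manifest["stages"][f"classify_{level}"] = summary.iloc[0].to_dict()

    # --- stage 3: feature modelling -------------------------------------
    for level, records in records_by_level.items():
        rbp_feat = rbp_feature_table(
            net,
            annotation,
            expr_rna,
            records,
            expr_protein=expr_protein,
            ppi_edges=ppi_edges,
            domain_counts=domain_counts,
            rbp_genes=rbp_genes,
        )
        p1 = outdir / f"rbp_features_{level}.tsv"
        write_feature_table(rbp_feat, p1)
        register(f"rbp_features_{level}", p1, len(rbp_feat))
        fits = {}
        if len(rbp_feat) > len(RBP_PREDICTORS) + 1:
            fits["multivariate"] = fit_multivariate(rbp_feat, "response", RBP_PREDICTORS)
            fits["stepwise"] = fit_stepwise(
                rbp_feat, "response", RBP_PREDICTORS, alpha_stay=config.alpha
            )
            fits["elastic_net"] = fit_elastic_net(
                rbp_feat, "response", RBP_PREDICTORS, seed=config.seed
            )
            fit_rows = [
                {
                    "method": m,
                    "feature": f,
                    "coefficient": fit.coefficients.get(f, 0.0),
                    "p_value": fit.feature_p.get(f, float("nan")),
                    "selected": f in fit.selected,
                }
                for m, fit in fits.items()
                for f in RBP_PREDICTORS
            ]
            p2 = outdir / f"rbp_model_{level}.tsv"
            write_feature_table(pd.DataFrame(fit_rows), p2)
            register(f"rbp_model_{level}", p2, len(fit_rows))
        else:
            manifest["warnings"].append(
                f"too few RBPs for RBP-centric modelling at {level} level"
            )
        tx_feat = transcript_feature_table(net, annotation, records)
        p3 = outdir / f"transcript_features_{level}.tsv"
        write_feature_table(tx_feat, p3)
        register(f"transcript_features_{level}", p3, len(tx_feat))
        if len(tx_feat):
            _, sig, fracs, skipped = per_rbp_transcript_models(
                tx_feat, alpha=config.alpha, seed=config.seed
            )
            p4 = outdir / f"transcript_model_significance_{level}.tsv"
            sig.to_csv(p4, sep="\t", index_label="rbp_id", float_format="%.6g")
            register(f"transcript_model_significance_{level}", p4, len(sig))
            p5 = outdir / f"transcript_model_fractions_{level}.tsv"
            write_feature_table(fracs, p5)
            register(f"transcript_model_fractions_{level}", p5, len(fracs))
            p6 = outdir / f"biotype_medians_{level}.tsv"
            write_feature_table(biotype_effect_summary(tx_feat), p6)
            register(f"biotype_medians_{level}", p6)
            if skipped:
                manifest["warnings"].append(
                    f"{level}: {len(skipped)} RBPs skipped in per-RBP models"
                )
        manifest["stages"][f"model_{level}"] = {"n_pairs": len(tx_feat)}

    # --- stage 4: centrality --------------------------------------------
    if ppi_edges and len(records_by_level) == 2:
        gene_label = lambda recs: [
            (rbp_genes[r.rbp_id], r.label) for r in recs
        ]
        sync, non_sync = sync_partition(
            gene_label(records_by_level["transcript"]),
            gene_label(records_by_level["protein"]),
        )
        cent = centralities(ppi_edges)
        cent_path = outdir / "centrality.tsv"
        cent_out = cent.copy()
        cent_out["group"] = [
            "sync" if v in sync else ("non_sync" if v in non_sync else "other")
            for v in cent_out.index
        ]
        cent_out.to_csv(cent_path, sep="\t", index_label="node", float_format="%.6g")
        register("centrality", cent_path, len(cent))
        stage: dict[str, Any] = {"n_sync": len(sync), "n_non_sync": len(non_sync)}
        if len(sync) >= 2 and len(non_sync) >= 2:
            for measure in ("closeness", "betweenness"):
                p, direction = compare_groups(cent, sync, non_sync, measure)
                stage[f"p_{measure}"] = p
                stage[f"direction_{measure}"] = direction
        manifest["stages"]["centrality"] = stage

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
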