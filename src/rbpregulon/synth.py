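"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generator emulates the structure of the real inputs — an exon-level
transcript annotation, per-RBP CLIP peak files, a transcript x tissue TPM
matrix, a matched gene x tissue protein-abundance matrix, a PPI edge list
and RNA-binding-domain counts — while recording every planted fact
(target sets, per-level SC/SIC/NSC labels, PPI core membership) in a truth
table, so that recovery by the pipeline can be scored exactly.

Planting strategy
-----------------
Each RBP gets a latent tissue profile; planted targets follow a monotone
coupling to that profile (positive for SC, negative for SIC, none for NSC)
plus Gaussian noise, then map through ``exp`` to positive TPM-like values.
Because the downstream statistic is Spearman, the coupling is calibrated
on ranks: a Gaussian-copula correlation of 2*sin(pi*rho_s/6) yields the
requested Spearman ``effect_rho``.  Protein profiles reuse the RNA latent
factor for RBPs planted with the same label at both levels ("sync") and an
independent factor otherwise, so label flips across levels are possible.

Peaks for planted pairs are placed inside a boundary window of the target;
decoy peaks are placed in a reserved zone more than 2*flank beyond every
exon boundary, so interval mapping recovers the planted network exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .formats import ExpressionMatrix, Peak, TranscriptRecord

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticData",
    "assign_default_labels",
    "generate",
    "write_fixtures",
]

_CHROMS = ("chr1", "chr2", "chr3", "chr4")


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic cohort; defaults mirror the real study's shape
    (60 RBPs, 16 RNA tissues, 9 matched protein tissues, 300 bp flank)."""

    seed: int = 0
    n_rbps: int = 60
    n_transcripts: int = 4500  # single-transcript candidate target genes
    n_multi_tx_genes: int = 50  # extra multi-transcript control genes
    n_tissues_rna: int = 16
    n_tissues_protein: int = 9
    planted_labels: dict[str, tuple[str, str]] | None = None  # rbp -> (rna, protein)
    effect_rho: float = Field(0.7, gt=0.0, lt=1.0)
    targets_per_rbp: tuple[int, int] = (50, 80)
    decoys_per_rbp: int = 20
    flank: int = 300
    noise_sd: float = 0.3  # floor on residual noise sd in the unit-variance latent
    biotype_distribution: dict[str, float] = Field(
        default_factory=lambda: {
            "protein_coding": 0.55,
            "processed_transcript": 0.20,
            "lincRNA": 0.15,
            "miRNA": 0.10,
        }
    )
    n_missing_protein: int = 2  # RBPs absent from the protein matrix
    ppi_core_planting: bool = True
    n_ppi_extra_proteins: int = 90

    @model_validator(mode="after")
    def _check(self):
        if self.n_tissues_protein > self.n_tissues_rna:
            raise ValueError("protein tissues must be a subset of RNA tissues")
        if self.targets_per_rbp[0] > self.targets_per_rbp[1]:
            raise ValueError("targets_per_rbp range inverted")
        return self


@dataclass
class SyntheticTruth:
    labels_transcript: dict[str, str]
    labels_protein: dict[str, str]
    targets: dict[str, list[str]]
    sync: set[str]
    ppi_core: set[str]
    rbp_genes: dict[str, str]
    missing_protein: set[str] = field(default_factory=set)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        rbps = sorted(self.labels_transcript)
        rbp_df = pd.DataFrame(
            {
                "rbp_id": rbps,
                "gene_id": [self.rbp_genes[r] for r in rbps],
                "label_transcript": [self.labels_transcript[r] for r in rbps],
                "label_protein": [self.labels_protein[r] for r in rbps],
                "sync": [r in self.sync for r in rbps],
                "in_ppi_core": [r in self.ppi_core for r in rbps],
                "has_protein_row": [r not in self.missing_protein for r in rbps],
                "n_targets": [len(self.targets[r]) for r in rbps],
            }
        )
        tgt_df = pd.DataFrame(
            [(r, t) for r in rbps for t in self.targets[r]],
            columns=["rbp_id", "transcript_id"],
        )
        return rbp_df, tgt_df


@dataclass
class SyntheticData:
    config: GeneratorConfig
    annotation: list[TranscriptRecord]
    peaks: list[Peak]
    expr_rna: ExpressionMatrix
    expr_protein: ExpressionMatrix
    ppi_edges: list[tuple[str, str]]
    domain_counts: dict[str, int]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# planted labels

_NONSYNC_CYCLE = [
    ("SC", "SIC"),
    ("SC", "NSC"),
    ("SIC", "NSC"),
    ("NSC", "SC"),
    ("NSC", "NSC"),
    ("SC", "SIC"),
]


def assign_default_labels(n_rbps: int) -> dict[str, tuple[str, str]]:
    """Deterministic label plan: six (SC,SC) and six (SIC,SIC) sync RBPs
    (when the cohort is large enough), then a fixed non-sync cycle."""
    out: dict[str, tuple[str, str]] = {}
    for i in range(n_rbps):
        rbp = f"RBP{i + 1:03d}"
        if i < 6:
            out[rbp] = ("SC", "SC")
        elif i < 12:
            out[rbp] = ("SIC", "SIC")
        else:
            out[rbp] = _NONSYNC_CYCLE[(i - 12) % len(_NONSYNC_CYCLE)]
    return out


# ---------------------------------------------------------------------------
# annotation


def _make_transcript(
    rng: np.random.Generator,
    tid: str,
    gene: str,
    biotype: str,
    chrom: str,
    strand: str,
    start: int,
    n_exons: int | None = None,
) -> TranscriptRecord:
    n_exons = n_exons or int(rng.integers(1, 11))
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(100, 601))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(700, 2001))  # intron
    return TranscriptRecord(tid, gene, biotype, chrom, strand, tuple(exons))


def _generate_annotation(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[TranscriptRecord], dict[str, str], list[str], dict[str, int]]:
    """Lay out genes along four chromosomes with inter-gene gaps wider than
    2*flank so boundary windows of different genes never overlap.

    Returns (records, rbp->gene map, candidate target transcript ids,
    per-chromosome end cursor for the decoy zone).
    """
    gap = 2 * cfg.flank + 200
    cursors = {c: 1000 for c in _CHROMS}
    records: list[TranscriptRecord] = []
    rbp_genes: dict[str, str] = {}
    biotypes = sorted(cfg.biotype_distribution)
    probs = np.array([cfg.biotype_distribution[b] for b in biotypes], float)
    probs /= probs.sum()

    # RBP genes: 1-3 transcripts, the first protein-coding (the representative)
    for i in range(cfg.n_rbps):
        rbp = f"RBP{i + 1:03d}"
        gene = rbp
        rbp_genes[rbp] = gene
        chrom = _CHROMS[i % len(_CHROMS)]
        strand = "+" if rng.random() < 0.5 else "-"
        main = _make_transcript(
            rng, f"{gene}.t1", gene, "protein_coding", chrom, strand, cursors[chrom]
        )
        records.append(main)
        end = main.genomic_end
        for j in range(int(rng.integers(0, 3))):
            sub = _make_transcript(
                rng,
                f"{gene}.t{j + 2}",
                gene,
                "processed_transcript" if rng.random() < 0.5 else "protein_coding",
                chrom,
                strand,
                main.genomic_start + int(rng.integers(0, 200)),
                n_exons=int(rng.integers(1, 4)),
            )
            records.append(sub)
            end = max(end, sub.genomic_end)
        cursors[chrom] = end + gap

    # single-transcript candidate target genes
    candidates = []
    for i in range(cfg.n_transcripts):
        tid = f"TX{i + 1:05d}"
        chrom = _CHROMS[i % len(_CHROMS)]
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = biotypes[rng.choice(len(biotypes), p=probs)]
        tx = _make_transcript(
            rng, tid, f"G_{tid}", biotype, chrom, strand, cursors[chrom],
            n_exons=int(rng.integers(1, 8)),
        )
        records.append(tx)
        candidates.append(tid)
        cursors[chrom] = tx.genomic_end + gap

    # multi-transcript control genes (never targeted; exercise gene->tx maps)
    for i in range(cfg.n_multi_tx_genes):
        gene = f"MG{i + 1:04d}"
        chrom = _CHROMS[i % len(_CHROMS)]
        strand = "+"
        start = cursors[chrom]
        end = start
        for j in range(2):
            tx = _make_transcript(
                rng, f"{gene}.t{j + 1}", gene,
                "protein_coding" if j == 0 else "processed_transcript",
                chrom, strand, start + j * 50, n_exons=int(rng.integers(1, 4)),
            )
            records.append(tx)
            end = max(end, tx.genomic_end)
        cursors[chrom] = end + gap
    return records, rbp_genes, candidates, cursors


# ---------------------------------------------------------------------------
# peaks


def _generate_peaks(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    annotation: list[TranscriptRecord],
    targets: dict[str, list[str]],
    decoy_cursors: dict[str, int],
) -> list[Peak]:
    tx_by_id = {t.transcript_id: t for t in annotation}
    flank = cfg.flank
    cursors = {c: v + 2 * flank + 100 for c, v in decoy_cursors.items()}
    peaks: list[Peak] = []

    def binding_p() -> float:
        return float(10.0 ** rng.uniform(-10, math.log10(0.05)))

    for rbp in sorted(targets):
        for tid in targets[rbp]:
            tx = tx_by_id[tid]
            boundaries = [b for s, e in tx.exons for b in (s, e - 1)]
            for _ in range(int(rng.integers(1, 3))):
                b = boundaries[rng.integers(len(boundaries))]
                width = int(rng.integers(20, 51))
                start = int(rng.integers(max(0, b - flank), b + flank))
                peaks.append(
                    Peak(rbp, tx.chrom, start, start + width, tx.strand, binding_p())
                )
        for _ in range(cfg.decoys_per_rbp):
            chrom = _CHROMS[rng.integers(len(_CHROMS))]
            width = int(rng.integers(20, 51))
            start = cursors[chrom]
            cursors[chrom] = start + width + 2 * flank + 100
            peaks.append(Peak(rbp, chrom, start, start + width, ".", binding_p()))
    return peaks


# ---------------------------------------------------------------------------
# expression


def _generate_expression(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    annotation: list[TranscriptRecord],
    truth: SyntheticTruth,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    n_rna, n_prot = cfg.n_tissues_rna, cfg.n_tissues_protein
    tissues = [f"tissue{i + 1:02d}" for i in range(n_rna)]
    rho_pearson = 2.0 * math.sin(math.pi * cfg.effect_rho / 6.0)
    sign = {"SC": 1.0, "SIC": -1.0, "NSC": 0.0}

    # latent tissue profiles per RBP: u drives the RNA level, v the protein
    # level; sync RBPs share one factor so labels agree across levels.
    # Non-sync v factors are standardized and orthogonalized against u
    # within the protein-tissue block and the remainder.  For RBPs where one
    # level is planted null while the other carries a coupling, chance
    # structure between the two profiles would shift the null level's whole
    # target rho distribution; candidates are therefore rejection-sampled
    # against a Monte-Carlo estimate of the very statistic the null level's
    # test averages (the expected Spearman of a coupled target against the
    # other profile), until that expectation is negligible.
    blocks = (
        [slice(0, n_prot), slice(n_prot, n_rna)]
        if n_rna - n_prot >= 3
        else [slice(0, n_rna)]
    )

    def _block_standardize(x: np.ndarray) -> np.ndarray:
        out = x.copy()
        for sl in blocks:
            b = out[sl] - out[sl].mean()
            out[sl] = b / b.std()
        return out

    def _orthogonalize(raw: np.ndarray, u_vec: np.ndarray) -> np.ndarray | None:
        w = raw.copy()
        for sl in blocks:
            b = w[sl] - w[sl].mean()
            ub = u_vec[sl] - u_vec[sl].mean()
            denom = float(ub @ ub)
            if denom > 0:
                b = b - (float(b @ ub) / denom) * ub
            sd = b.std()
            if sd < 1e-8:
                return None
            w[sl] = b / sd
        return w

    def _mean_null_spearman(
        probe: np.ndarray, coupled: np.ndarray, weight: float, resid: float,
        m: int = 2000,
    ) -> float:
        """MC estimate of E[spearman(weight*coupled + resid*noise, probe)]."""
        from .classify import spearman_profile

        sims = weight * coupled + resid * rng.standard_normal((m, len(coupled)))
        rho, _ = spearman_profile(probe, sims)
        return float(np.nanmean(rho))

    labels_t, labels_p = truth.labels_transcript, truth.labels_protein

    def _weights(rbp: str, shared: bool) -> tuple[float, float, float]:
        s_r, s_p = sign[labels_t[rbp]], sign[labels_p[rbp]]
        k = int(s_r != 0) + int(s_p != 0 and not shared)
        if k == 0:
            return 0.0, 0.0, 1.0
        w = min(rho_pearson, math.sqrt((1.0 - cfg.noise_sd**2) / k))
        w_u = w * s_r
        w_v = 0.0 if shared else w * s_p
        resid = math.sqrt(max(1.0 - w_u**2 - w_v**2, cfg.noise_sd**2))
        return w_u, w_v, resid

    u: dict[str, np.ndarray] = {}
    v: dict[str, np.ndarray] = {}
    shared_factor: dict[str, bool] = {}
    for rbp in sorted(labels_t):
        u[rbp] = _block_standardize(rng.standard_normal(n_rna))
        shared_factor[rbp] = (
            labels_t[rbp] == labels_p[rbp] and labels_t[rbp] in {"SC", "SIC"}
        )
        if shared_factor[rbp]:
            v[rbp] = u[rbp].copy()
            continue
        w_u, w_v, resid = _weights(rbp, shared=False)
        null_transcript = labels_t[rbp] == "NSC" and w_v != 0.0
        null_protein = labels_p[rbp] == "NSC" and w_u != 0.0
        best, best_score = None, math.inf
        for _ in range(80):
            cand = _orthogonalize(rng.standard_normal(n_rna), u[rbp])
            if cand is None:
                continue
            score = 0.0
            if null_transcript:
                # transcript test sees spearman(target, u) over all tissues
                score = abs(
                    _mean_null_spearman(u[rbp], cand, w_v, resid)
                )
            elif null_protein:
                # protein test sees spearman(target, v) over shared tissues
                score = abs(
                    _mean_null_spearman(
                        cand[:n_prot], u[rbp][:n_prot], w_u, resid, m=3000
                    )
                )
            if score < best_score:
                best, best_score = cand, score
            if best_score <= 0.008:
                break
        v[rbp] = best if best is not None else u[rbp] * 0.0

    driver: dict[str, tuple[str, float, float]] = {}  # tid -> (rbp, w_u, w_v)
    for rbp in sorted(truth.targets):
        w_u, w_v, resid = _weights(rbp, shared_factor[rbp])
        if w_u == 0.0 and w_v == 0.0:
            continue
        for tid in truth.targets[rbp]:
            driver[tid] = (rbp, w_u, w_v)

    rows, index = [], []
    rep_mean: dict[str, float] = {}
    rbp_gene_set = set(truth.rbp_genes.values())
    for tx in annotation:
        tid = tx.transcript_id
        if tx.gene_id in rbp_gene_set and tid.endswith(".t1"):
            # representative transcript of an RBP: tracks u with little noise
            rbp = tx.gene_id
            z = u[rbp] + 0.04 * rng.standard_normal(n_rna)
            base = 3.0
            row = np.exp(base + 1.2 * z)
            rep_mean[tx.gene_id] = float(row.mean())
            rows.append(row)
            index.append(tid)
            continue
        if tx.gene_id in rbp_gene_set:
            # sibling transcripts of an RBP gene: uncoupled noise, rescaled
            # below the representative so the highest-mean rule picks .t1
            row = np.exp(1.2 * rng.standard_normal(n_rna))
            row *= rep_mean[tx.gene_id] * rng.uniform(0.1, 0.6) / row.mean()
            rows.append(row)
            index.append(tid)
            continue
        if tid in driver:
            rbp, w_u, w_v = driver[tid]
            resid = math.sqrt(max(1.0 - w_u**2 - w_v**2, cfg.noise_sd**2))
            z = w_u * u[rbp] + w_v * v[rbp] + resid * rng.standard_normal(n_rna)
            base = float(rng.normal(1.5, 1.0))
        else:
            z = rng.standard_normal(n_rna)
            base = float(rng.normal(1.5, 1.0))
        rows.append(np.exp(base + 1.2 * z))
        index.append(tid)
    expr_rna = ExpressionMatrix(
        pd.DataFrame(rows, index=index, columns=tissues), level="transcript"
    )

    prot_rows, prot_index = [], []
    for rbp in sorted(truth.labels_transcript):
        if rbp in truth.missing_protein:
            continue
        z = v[rbp][:n_prot] + 0.04 * rng.standard_normal(n_prot)
        prot_rows.append(np.exp(3.0 + z))
        prot_index.append(truth.rbp_genes[rbp])
    expr_protein = ExpressionMatrix(
        pd.DataFrame(prot_rows, index=prot_index, columns=tissues[:n_prot]),
        level="protein",
    )
    return expr_rna, expr_protein


# ---------------------------------------------------------------------------
# PPI and domain counts


def _generate_ppi(
    cfg: GeneratorConfig, rng: np.random.Generator, truth: SyntheticTruth
) -> tuple[list[tuple[str, str]], set[str]]:
    """Random PPI graph over RBP genes plus bystander proteins.

    With core planting, sync RBPs attach densely to a small clique-like
    core, giving them shorter path lengths (higher closeness) than
    peripheral non-sync RBPs; with planting off all RBPs attach uniformly.
    """
    extras = [f"P{i + 1:04d}" for i in range(cfg.n_ppi_extra_proteins)]
    rbp_nodes = [truth.rbp_genes[r] for r in sorted(truth.rbp_genes)]
    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a <= b else (b, a))

    for i, a in enumerate(extras):
        for b in extras[i + 1 :]:
            if rng.random() < 0.04:
                add(a, b)
    core: set[str] = set()
    if cfg.ppi_core_planting:
        core_extras = extras[:12]
        core = set(core_extras) | {truth.rbp_genes[r] for r in truth.sync}
        core_sorted = sorted(core)
        for i, a in enumerate(core_sorted):
            for b in core_sorted[i + 1 :]:
                if rng.random() < 0.7:
                    add(a, b)
        periphery = extras[12:]
        for rbp in sorted(truth.rbp_genes.values()):
            if rbp not in core:
                for _ in range(int(rng.integers(1, 3))):
                    add(rbp, periphery[rng.integers(len(periphery))])
    else:
        for rbp in rbp_nodes:
            for _ in range(int(rng.integers(1, 3))):
                add(rbp, extras[rng.integers(len(extras))])

    # stitch components together so all RBPs share the main component
    import networkx as nx

    g = nx.Graph(sorted(edges))
    g.add_nodes_from(rbp_nodes + extras)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    anchor = min(comps[0])
    for comp in comps[1:]:
        add(anchor, min(comp))
    return sorted(edges), core


def generate(cfg: GeneratorConfig) -> SyntheticData:
    """Generate the full synthetic cohort; deterministic in ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    labels = cfg.planted_labels or assign_default_labels(cfg.n_rbps)
    rbps = sorted(labels)
    labels_t = {r: labels[r][0] for r in rbps}
    labels_p = {r: labels[r][1] for r in rbps}
    sync = {r for r in rbps if labels_t[r] == labels_p[r] and labels_t[r] != "NSC"}

    annotation, rbp_genes, candidates, cursors = _generate_annotation(cfg, rng)

    # coupled RBPs (any planted effect) get disjoint target sets so each
    # transcript is driven by at most one latent factor; fully-null RBPs may
    # share targets freely
    sizes = {r: int(rng.integers(cfg.targets_per_rbp[0], cfg.targets_per_rbp[1] + 1)) for r in rbps}
    coupled = [r for r in rbps if labels_t[r] != "NSC" or labels_p[r] != "NSC"]
    need = sum(sizes[r] for r in coupled)
    if need > len(candidates):
        raise ValueError(
            f"{need} coupled targets requested but only {len(candidates)} "
            "candidate transcripts; increase n_transcripts"
        )
    pool = list(rng.permutation(candidates))
    targets: dict[str, list[str]] = {}
    pos = 0
    for r in coupled:
        targets[r] = sorted(pool[pos : pos + sizes[r]])
        pos += sizes[r]
    for r in rbps:
        if r not in targets:
            targets[r] = sorted(
                rng.choice(np.array(candidates), size=sizes[r], replace=False)
            )
    missing = set(rbps[-cfg.n_missing_protein :]) if cfg.n_missing_protein else set()
    truth = SyntheticTruth(
        labels_transcript=labels_t,
        labels_protein=labels_p,
        targets=targets,
        sync=sync,
        ppi_core=set(),
        rbp_genes=rbp_genes,
        missing_protein=missing,
    )
    peaks = _generate_peaks(cfg, rng, annotation, targets, cursors)
    expr_rna, expr_protein = _generate_expression(cfg, rng, annotation, truth)
    ppi_edges, core = _generate_ppi(cfg, rng, truth)
    truth.ppi_core = {r for r in rbps if rbp_genes[r] in core}
    domain_counts = {
        rbp_genes[r]: int(rng.integers(1, 15)) for r in rbps
    }
    return SyntheticData(
        cfg, annotation, peaks, expr_rna, expr_protein, ppi_edges, domain_counts, truth
    )


# ---------------------------------------------------------------------------
# file output


def write_fixtures(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture to ``outdir``; byte-identical for identical configs."""
    from .formats import write_edge_list, write_expression

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for tx in data.annotation:
            for s, e in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'transcript_biotype "{tx.biotype}";'
                )
                fh.write(
                    f"{tx.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
    paths["annotation"] = gtf

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    by_rbp: dict[str, list[Peak]] = {}
    for p in data.peaks:
        by_rbp.setdefault(p.rbp_id, []).append(p)
    for rbp, plist in sorted(by_rbp.items()):
        path = peak_dir / f"{rbp}.bed"
        with open(path, "w") as fh:
            for i, p in enumerate(
                sorted(plist, key=lambda q: (q.chrom, q.start, q.end))
            ):
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{rbp}_pk{i + 1}\t"
                    f"{p.binding_p:.6e}\t{p.strand}\n"
                )
        paths[f"peaks/{rbp}"] = path

    paths["expr_rna"] = outdir / "expression_rna.tsv"
    write_expression(data.expr_rna, paths["expr_rna"])
    paths["expr_protein"] = outdir / "expression_protein.tsv"
    write_expression(data.expr_protein, paths["expr_protein"])
    paths["ppi"] = outdir / "ppi.tsv"
    write_edge_list(data.ppi_edges, paths["ppi"])

    paths["domains"] = outdir / "domains.tsv"
    with open(paths["domains"], "w") as fh:
        fh.write("gene_id\tn_rna_binding_domains\n")
        for gene, n in sorted(data.domain_counts.items()):
            fh.write(f"{gene}\t{n}\n")

    rbp_df, tgt_df = data.truth.to_frames()
    paths["truth_rbps"] = outdir / "truth_rbps.tsv"
    rbp_df.to_csv(paths["truth_rbps"], sep="\t", index=False)
    paths["truth_targets"] = outdir / "truth_targets.tsv"
    tgt_df.to_csv(paths["truth_targets"], sep="\t", index=False)
    return paths
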