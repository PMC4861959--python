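"""Classify each RBP's co-expression with its targets as SC / SIC / NSC.

For every RBP, transcripts with expression data are split into targets,
matched controls (``n_reps`` random non-target samples of target-set size)
and the full non-target control set.  Spearman correlation between the
RBP's expression profile and each transcript's profile across tissues
yields per-category correlation distributions; a two-sided Wilcoxon
rank-sum (Mann-Whitney) test against the control distribution labels the
RBP:

* SC  (significantly congruent)   — p < alpha, median target rho higher
* SIC (significantly incongruent) — p < alpha, median target rho lower
* NSC (no significant change)     — otherwise

At the transcript level the RBP profile is the expression of its
representative transcript (the protein-coding transcript with the highest
mean expression).  At the protein level the RBP profile comes from a
protein-abundance matrix and the target/control profiles from the RNA
matrix restricted to the tissues shared by both compendia.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ExpressionMatrix, TranscriptRecord
from .network import TargetNetwork

__all__ = [
    "TranscriptPartition",
    "ClassificationRecord",
    "select_representative",
    "spearman_profile",
    "partition",
    "classify",
    "run_level",
    "class_summary",
]

LABELS = ("SC", "SIC", "NSC")


@dataclass
class TranscriptPartition:
    """Target / control-all / matched-control split for one RBP."""

    rbp_id: str
    targets: list[str]
    control_all: list[str]
    control_matched_samples: list[list[str]] = field(default_factory=list)


@dataclass
class ClassificationRecord:
    rbp_id: str
    level: str
    representative_id: str
    rho_targets: np.ndarray
    rho_control_all: np.ndarray
    p_vs_all: float
    p_vs_matched: np.ndarray
    p_matched_summary: float
    label: str
    alpha: float = 0.05
    flag: str = ""
    target_ids: list[str] = field(default_factory=list)
    control_ids: list[str] = field(default_factory=list)

    @property
    def median_target_rho(self) -> float:
        return float(np.median(self.rho_targets)) if len(self.rho_targets) else np.nan

    @property
    def median_control_rho(self) -> float:
        return (
            float(np.median(self.rho_control_all))
            if len(self.rho_control_all)
            else np.nan
        )

    def matched_agreement(self) -> float:
        """Fraction of matched resamples whose test agrees with the final label."""
        if len(self.p_vs_matched) == 0:
            return np.nan
        sig = self.p_vs_matched < self.alpha
        return float(np.mean(sig if self.label != "NSC" else ~sig))

    def to_row(self) -> dict:
        return {
            "rbp_id": self.rbp_id,
            "level": self.level,
            "representative_id": self.representative_id,
            "n_targets": len(self.rho_targets),
            "median_target_rho": self.median_target_rho,
            "median_control_rho": self.median_control_rho,
            "p_all": self.p_vs_all,
            "p_matched_summary": self.p_matched_summary,
            "matched_agreement": self.matched_agreement(),
            "label": self.label,
            "flag": self.flag,
        }

    def long_rows(self) -> pd.DataFrame:
        """Per-transcript rho values, for transcript-centric modelling."""
        n_t, n_c = len(self.target_ids), len(self.control_ids)
        return pd.DataFrame(
            {
                "rbp_id": self.rbp_id,
                "level": self.level,
                "transcript_id": list(self.target_ids) + list(self.control_ids),
                "rho": np.concatenate([self.rho_targets, self.rho_control_all])
                if n_t + n_c
                else [],
                "is_target": [True] * n_t + [False] * n_c,
            }
        )


# ---------------------------------------------------------------------------


def select_representative(
    rbp_gene: str,
    annotation: Sequence[TranscriptRecord],
    expr: ExpressionMatrix,
) -> str | None:
    """Pick the RBP's representative transcript.

    The protein-coding transcript of the gene with the highest mean
    expression across all tissues; ties broken by lexicographically
    smallest transcript id.  Returns None when the gene has no
    protein-coding transcript with an expression row.
    """
    candidates = [
        t.transcript_id
        for t in annotation
        if t.gene_id == rbp_gene
        and t.biotype == "protein_coding"
        and t.transcript_id in expr.data.index
    ]
    if not candidates:
        return None
    means = expr.data.loc[candidates].mean(axis=1)
    best = means.max()
    return sorted(means.index[means == best])[0]


def spearman_profile(
    x: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho between profile ``x`` and every row of ``Y``.

    Ranks use midranks for ties (identical to ``scipy.stats.spearmanr``).
    Rows that are constant (zero rank variance) have undefined rho and are
    returned as NaN together with a boolean validity mask; callers exclude
    and count them.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = x.shape[0]
    if n < 3:
        raise ValueError("need >=3 paired tissues for Spearman correlation")
    if Y.shape[1] != n:
        raise ValueError("profile and matrix tissue dimensions differ")
    rx = stats.rankdata(x)
    rY = stats.rankdata(Y, axis=1)
    rx_c = rx - rx.mean()
    rY_c = rY - rY.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum()) * np.sqrt((rY_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rY_c @ rx_c) / denom
    valid = denom > 0
    rho[~valid] = np.nan
    return rho, valid


def _rbp_rng(seed: int, rbp_id: str) -> np.random.Generator:
    # deterministic per-RBP stream regardless of iteration order
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(rbp_id.encode())])


def partition(
    rbp_id: str,
    net: TargetNetwork,
    expr: ExpressionMatrix,
    n_reps: int = 100,
    seed: int = 0,
    exclude_rows: Iterable[str] = (),
) -> TranscriptPartition:
    """Split expressed transcripts into targets / control-all / matched samples.

    Matched samples are drawn without replacement from the non-target pool,
    each the size of the target set, reproducibly from ``seed`` (one
    independent stream per RBP).  ``exclude_rows`` removes rows (e.g. the
    RBP's own representative transcript) from the control pool.
    """
    expressed = set(expr.data.index)
    targets = sorted(net.targets.get(rbp_id, set()) & expressed)
    excluded = set(exclude_rows)
    control_all = sorted(
        expressed - set(net.targets.get(rbp_id, set())) - excluded
    )
    if len(control_all) < len(targets):
        raise ValueError(
            f"{rbp_id}: control pool ({len(control_all)}) smaller than "
            f"target set ({len(targets)}); matched sampling impossible"
        )
    rng = _rbp_rng(seed, rbp_id)
    ctrl_arr = np.array(control_all)
    samples = [
        list(rng.choice(ctrl_arr, size=len(targets), replace=False))
        for _ in range(n_reps)
    ]
    return TranscriptPartition(rbp_id, targets, control_all, samples)


def classify(
    rho_targets: np.ndarray,
    rho_controls: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, str]:
    """Two-sided rank-sum test of target vs control rho distributions.

    Returns (p, label).  With fewer than two values on either side the
    comparison is not meaningful: p is NaN and the label NSC (callers flag
    this as insufficient data).
    """
    rho_targets = np.asarray(rho_targets, float)
    rho_controls = np.asarray(rho_controls, float)
    if len(rho_targets) < 2 or len(rho_controls) < 2:
        return np.nan, "NSC"
    pooled = np.concatenate([rho_targets, rho_controls])
    if np.all(pooled == pooled[0]):  # rank-sum degenerate: no variation at all
        return 1.0, "NSC"
    p = float(
        stats.mannwhitneyu(
            rho_targets, rho_controls, alternative="two-sided", method="asymptotic"
        ).pvalue
    )
    if p < alpha:
        label = (
            "SC" if np.median(rho_targets) > np.median(rho_controls) else "SIC"
        )
    else:
        label = "NSC"
    return p, label


def run_level(
    rbp_genes: dict[str, str],
    net: TargetNetwork,
    expr_rna: ExpressionMatrix,
    annotation: Sequence[TranscriptRecord],
    expr_protein: ExpressionMatrix | None = None,
    level: str = "transcript",
    alpha: float = 0.05,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[list[ClassificationRecord], pd.DataFrame]:
    """Classify every RBP at one level; returns records + a summary table.

    ``rbp_genes`` maps rbp_id -> gene id.  At level "protein" the RBP
    profile is its gene's row of ``expr_protein`` and target/control
    profiles come from ``expr_rna`` restricted to the shared tissues; RBPs
    without a protein row are skipped and reported in the summary.
    """
    if level not in {"transcript", "protein"}:
        raise ValueError(f"unknown level {level!r}")
    if level == "protein":
        if expr_protein is None:
            raise ValueError("protein level requires a protein expression matrix")
        shared = [t for t in expr_protein.tissue_ids if t in expr_rna.tissue_ids]
        if len(shared) < 3:
            raise ValueError(
                f"only {len(shared)} tissues shared between RNA and protein "
                "matrices; need >=3"
            )
        rna = expr_rna.data[shared]
    else:
        rna = expr_rna.data

    records: list[ClassificationRecord] = []
    skipped: list[str] = []
    for rbp_id in sorted(rbp_genes):
        gene = rbp_genes[rbp_id]
        rep = select_representative(gene, annotation, expr_rna)
        if level == "transcript":
            if rep is None:
                skipped.append(rbp_id)
                continue
            x = rna.loc[rep].to_numpy()
            rep_id = rep
        else:
            if gene not in expr_protein.data.index:
                skipped.append(rbp_id)
                continue
            x = expr_protein.data.loc[gene, shared].to_numpy(dtype=float)
            rep_id = gene
        exclude = {rep} if rep is not None else set()
        part = partition(
            rbp_id, net, ExpressionMatrix(rna, level=expr_rna.level),
            n_reps=n_reps, seed=seed, exclude_rows=exclude,
        )
        rho_t, valid_t = spearman_profile(x, rna.loc[part.targets].to_numpy()) \
            if part.targets else (np.array([]), np.array([], bool))
        rho_c, valid_c = spearman_profile(x, rna.loc[part.control_all].to_numpy())
        t_ids = [tid for tid, v in zip(part.targets, valid_t) if v]
        c_ids = [cid for cid, v in zip(part.control_all, valid_c) if v]
        rho_t, rho_c = rho_t[valid_t], rho_c[valid_c]
        p_all, label = classify(rho_t, rho_c, alpha=alpha)
        rho_c_series = pd.Series(rho_c, index=c_ids)
        p_matched = []
        for sample in part.control_matched_samples:
            sample_rho = rho_c_series.reindex(sample).dropna().to_numpy()
            p_m, _ = classify(rho_t, sample_rho, alpha=alpha)
            p_matched.append(p_m)
        p_matched = np.array(p_matched, float)
        flag = ""
        if np.isnan(p_all):
            flag = "insufficient_data"
        records.append(
            ClassificationRecord(
                rbp_id=rbp_id,
                level=level,
                representative_id=rep_id,
                rho_targets=rho_t,
                rho_control_all=rho_c,
                p_vs_all=p_all,
                p_vs_matched=p_matched,
                p_matched_summary=float(np.nanmedian(p_matched))
                if len(p_matched)
                else np.nan,
                label=label,
                alpha=alpha,
                flag=flag,
                target_ids=t_ids,
                control_ids=c_ids,
            )
        )
    summary = class_summary([r.label for r in records])
    summary["skipped_rbps"] = ",".join(skipped)
    return records, pd.DataFrame([summary])


def class_summary(labels: Iterable[str] | dict[str, int]) -> dict:
    """Counts and percentages of the SC / SIC / NSC labels.

    Accepts either an iterable of labels or a precomputed count map.
    Percentages are over all classified RBPs; ``pct_*_of_significant``
    are over the SC+SIC subset.
    """
    if isinstance(labels, dict):
        counts = {k: int(labels.get(k, 0)) for k in LABELS}
    else:
        labels = list(labels)
        counts = {k: labels.count(k) for k in LABELS}
    n = sum(counts.values())
    n_sig = counts["SC"] + counts["SIC"]
    pct = lambda a, b: round(100.0 * a / b, 2) if b else np.nan
    return {
        "n": n,
        "n_SC": counts["SC"],
        "n_SIC": counts["SIC"],
        "n_NSC": counts["NSC"],
        "pct_SC": pct(counts["SC"], n),
        "pct_SIC": pct(counts["SIC"], n),
        "pct_NSC": pct(counts["NSC"], n),
        "pct_significant": pct(n_sig, n),
        "pct_SC_of_significant": pct(counts["SC"], n_sig),
        "pct_SIC_of_significant": pct(counts["SIC"], n_sig),
    }
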