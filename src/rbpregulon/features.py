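"""Feature tables and feature-selection models for RBP-target correlations.

Two complementary views ask *why* an RBP correlates with its targets:

* RBP-centric — one row per RBP; the response is the median Spearman rho
  of its targets and the predictors are properties of the RBP itself
  (target count, CLIP signal, RNA-binding domains, PPI degree, transcript
  repertoire, binding-site geometry, mRNA-protein correlation).
* transcript-centric — one row per (RBP, target) pair; the response is
  that pair's rho and the predictors are properties of the pair (CLIP
  signal, binding-site distance from the 5'/3' transcript ends, transcript
  length and biotype).

Three procedures rank the predictors: full multivariate OLS, backward
stepwise elimination, and cross-validated elastic net.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .classify import select_representative
from .formats import ExpressionMatrix, TranscriptRecord
from .network import TargetNetwork

__all__ = [
    "ModelFit",
    "RBP_PREDICTORS",
    "TRANSCRIPT_PREDICTORS",
    "rbp_feature_table",
    "transcript_feature_table",
    "fit_multivariate",
    "fit_stepwise",
    "fit_elastic_net",
    "per_rbp_transcript_models",
    "biotype_effect_summary",
]

RBP_PREDICTORS = [
    "n_targets",
    "median_clip_p",
    "n_rna_binding_domains",
    "n_ppi_partners",
    "n_protein_coding_transcripts",
    "n_annotated_transcripts",
    "selected_transcript_length",
    "median_boundary_distance",
    "mrna_protein_corr",
]

TRANSCRIPT_PREDICTORS = [
    "clip_p",
    "dist_5prime",
    "dist_3prime",
    "transcript_length",
    "transcript_type",
]


@dataclass
class ModelFit:
    method: str  # multivariate | stepwise | elastic_net
    scope: str  # rbp_id or "global"
    coefficients: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    selected: set[str] = field(default_factory=set)
    hyperparameters: dict = field(default_factory=dict)
    feature_p: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# feature tables


def _end_distances(peak_start: int, tx: TranscriptRecord) -> tuple[int, int]:
    """Distances from a peak start to the strand-aware 5' and 3' transcript
    ends, measured on the genomic span (not spliced coordinates)."""
    left = abs(peak_start - tx.genomic_start)
    right = abs(tx.genomic_end - 1 - peak_start)
    return (left, right) if tx.strand == "+" else (right, left)


def rbp_feature_table(
    net: TargetNetwork,
    annotation: Sequence[TranscriptRecord],
    expr_rna: ExpressionMatrix,
    classification: Sequence,
    expr_protein: ExpressionMatrix | None = None,
    ppi_edges: Sequence[tuple[str, str]] = (),
    domain_counts: dict[str, int] | None = None,
    rbp_genes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per classified RBP with the RBP-centric predictors.

    Missing domain-count or PPI entries become 0 with a provenance flag;
    a missing protein profile sets ``mrna_protein_corr`` to 0 with a flag
    so the design matrix stays complete.
    """
    tx_by_id = {t.transcript_id: t for t in annotation}
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for t in annotation:
        by_gene.setdefault(t.gene_id, []).append(t)
    degree: dict[str, int] = {}
    for a, b in ppi_edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    domain_counts = domain_counts or {}
    rbp_genes = rbp_genes or {}

    shared = (
        [t for t in expr_protein.tissue_ids if t in expr_rna.tissue_ids]
        if expr_protein is not None
        else []
    )
    rows = []
    for rec in classification:
        rbp = rec.rbp_id
        gene = rbp_genes.get(rbp, rbp)
        flags = []
        clip_ps, boundary_dists = [], []
        for tid in net.targets.get(rbp, set()):
            for pk in net.supporting_peaks.get((rbp, tid), []):
                clip_ps.append(pk.binding_p)
                tx = tx_by_id.get(tid)
                if tx is not None:
                    boundary_dists.append(min(_end_distances(pk.start, tx)))
        gene_txs = by_gene.get(gene, [])
        # the selected transcript is always the RNA-level representative,
        # whatever level the classification records came from
        rep_id = select_representative(gene, gene_txs, expr_rna)
        rep_len = next(
            (t.length for t in gene_txs if t.transcript_id == rep_id), 0
        )
        if gene in domain_counts:
            n_domains = domain_counts[gene]
        elif rbp in domain_counts:
            n_domains = domain_counts[rbp]
        else:
            n_domains, _ = 0, flags.append("no_domain_entry")
        if gene in degree or rbp in degree:
            n_ppi = degree.get(gene, degree.get(rbp, 0))
        else:
            n_ppi, _ = 0, flags.append("no_ppi_entry")
        corr = 0.0
        if (
            expr_protein is not None
            and gene in expr_protein.data.index
            and rep_id is not None
            and len(shared) >= 3
        ):
            corr = float(
                stats.spearmanr(
                    expr_rna.data.loc[rep_id, shared],
                    expr_protein.data.loc[gene, shared],
                ).statistic
            )
            if np.isnan(corr):
                corr, _ = 0.0, flags.append("constant_profile")
        else:
            flags.append("no_protein_profile")
        rows.append(
            {
                "rbp_id": rbp,
                "response": rec.median_target_rho,
                "n_targets": len(net.targets.get(rbp, set())),
                "median_clip_p": float(np.median(clip_ps)) if clip_ps else 1.0,
                "n_rna_binding_domains": n_domains,
                "n_ppi_partners": n_ppi,
                "n_protein_coding_transcripts": sum(
                    1 for t in gene_txs if t.biotype == "protein_coding"
                ),
                "n_annotated_transcripts": len(gene_txs),
                "selected_transcript_length": rep_len,
                "median_boundary_distance": float(np.median(boundary_dists))
                if boundary_dists
                else 0.0,
                "mrna_protein_corr": corr,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def transcript_feature_table(
    net: TargetNetwork,
    annotation: Sequence[TranscriptRecord],
    classification: Sequence,
) -> pd.DataFrame:
    """One row per (RBP, target transcript) pair with Table-style predictors.

    When several peaks support one pair the peak with the smallest binding
    p-value represents it.  Pairs lacking an expression-backed rho are
    excluded (their count is available as the difference from the network).
    """
    tx_by_id = {t.transcript_id: t for t in annotation}
    rows = []
    for rec in classification:
        rho_by_tid = dict(zip(rec.target_ids, rec.rho_targets))
        for tid in sorted(net.targets.get(rec.rbp_id, set())):
            if tid not in rho_by_tid or tid not in tx_by_id:
                continue
            peaks = net.supporting_peaks.get((rec.rbp_id, tid), [])
            if not peaks:
                continue
            best = min(peaks, key=lambda p: (p.binding_p, p.start))
            tx = tx_by_id[tid]
            d5, d3 = _end_distances(best.start, tx)
            rows.append(
                {
                    "rbp_id": rec.rbp_id,
                    "transcript_id": tid,
                    "response": rho_by_tid[tid],
                    "clip_p": best.binding_p,
                    "dist_5prime": d5,
                    "dist_3prime": d3,
                    "transcript_length": tx.length,
                    "transcript_type": tx.biotype,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model fitting


def _build_design(
    table: pd.DataFrame, predictors: Sequence[str], merge_singletons: bool = True
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expand categoricals into indicator contrasts against a reference level.

    Returns the numeric design matrix and a map design column -> parent
    feature.  Categorical levels observed only once are merged into
    "other" so contrasts remain estimable.
    """
    cols, parent = [], {}
    for feat in predictors:
        col = table[feat]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            vals = col.astype(str)
            if merge_singletons:
                counts = vals.value_counts()
                rare = set(counts.index[counts < 2])
                if rare:
                    vals = vals.where(~vals.isin(rare), "other")
            levels = sorted(vals.unique())
            for lev in levels[1:]:  # first (sorted) level is the reference
                name = f"{feat}[{lev}]"
                cols.append((vals == lev).astype(float).rename(name))
                parent[name] = feat
        else:
            cols.append(col.astype(float))
            parent[feat] = feat
    X = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=table.index)
    return X, parent


def _check_full_rank(X: pd.DataFrame) -> None:
    # columns scaled to unit norm so the rank tolerance is scale-free
    mat = np.column_stack([np.ones(len(X)), X.to_numpy()])
    norms = np.linalg.norm(mat, axis=0)
    norms[norms == 0] = 1.0
    mat = mat / norms
    if np.linalg.matrix_rank(mat, tol=1e-8) < mat.shape[1]:
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i - 1] for i in np.where(diag < 1e-8)[0] if i > 0]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def _feature_pvalues(
    p_by_col: dict[str, float], parent: dict[str, str]
) -> dict[str, float]:
    """Per-feature significance: a numeric feature keeps its coefficient p;
    a categorical feature takes the minimum BH-adjusted p over its contrasts."""
    groups: dict[str, list[str]] = {}
    for col, feat in parent.items():
        groups.setdefault(feat, []).append(col)
    out = {}
    for feat, cols in groups.items():
        ps = np.array([p_by_col[c] for c in cols])
        if len(ps) == 1:
            out[feat] = float(ps[0])
        else:
            out[feat] = float(multipletests(ps, method="fdr_bh")[1].min())
    return out


def fit_multivariate(
    table: pd.DataFrame,
    response: str = "response",
    predictors: Sequence[str] | None = None,
    scope: str = "global",
) -> ModelFit:
    """Ordinary least squares on all predictors, with per-coefficient
    two-sided t-test p-values."""
    predictors = list(predictors or [c for c in table.columns if c != response])
    X, parent = _build_design(table, predictors)
    if len(table) <= X.shape[1] + 1:
        raise ValueError(
            f"need more rows ({len(table)}) than predictors+1 ({X.shape[1] + 1})"
        )
    _check_full_rank(X)
    fit = sm.OLS(table[response].to_numpy(float), sm.add_constant(X)).fit()
    p_by_col = {c: float(fit.pvalues[c]) for c in X.columns}
    feature_p = _feature_pvalues(p_by_col, parent)
    return ModelFit(
        method="multivariate",
        scope=scope,
        coefficients={c: float(fit.params[c]) for c in X.columns},
        p_values=p_by_col,
        selected={f for f, p in feature_p.items() if p < 0.05},
        feature_p=feature_p,
    )


def fit_stepwise(
    table: pd.DataFrame,
    response: str = "response",
    predictors: Sequence[str] | None = None,
    alpha_stay: float = 0.05,
    scope: str = "global",
) -> ModelFit:
    """Backward elimination: refit OLS and drop the least significant
    feature while its p-value is >= ``alpha_stay``.

    Deterministic: ties in the worst p-value break on lexicographic feature
    name, so the result does not depend on column order.  Eliminating every
    predictor leaves a valid intercept-only fit.
    """
    predictors = list(predictors or [c for c in table.columns if c != response])
    remaining = sorted(predictors)
    y = table[response].to_numpy(float)
    feature_p: dict[str, float] = {}
    coefficients: dict[str, float] = {}
    while remaining:
        X, parent = _build_design(table, remaining)
        _check_full_rank(X)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        p_by_col = {c: float(fit.pvalues[c]) for c in X.columns}
        feature_p = _feature_pvalues(p_by_col, parent)
        worst = max(sorted(feature_p), key=lambda f: (feature_p[f], f))
        if feature_p[worst] < alpha_stay:
            coefficients = {c: float(fit.params[c]) for c in X.columns}
            break
        remaining.remove(worst)
    else:
        feature_p, coefficients = {}, {}
    return ModelFit(
        method="stepwise",
        scope=scope,
        coefficients=coefficients,
        p_values=feature_p,
        selected=set(remaining),
        feature_p=feature_p,
        hyperparameters={"alpha_stay": alpha_stay},
    )


def fit_elastic_net(
    table: pd.DataFrame,
    response: str = "response",
    predictors: Sequence[str] | None = None,
    l1_ratio_grid: Sequence[float] = (0.1, 0.5, 0.9, 1.0),
    lambda_grid: Sequence[float] | None = None,
    k_folds: int = 10,
    seed: int = 0,
    scope: str = "global",
) -> ModelFit:
    """Elastic-net regression with hyperparameters chosen by k-fold CV MSE.

    Predictors are standardized (zero mean, unit variance) and the response
    centered before penalization; "selected" features are those with at
    least one nonzero coefficient at the chosen (l1_ratio, lambda).  When a
    single l1_ratio and a single lambda are supplied the model is fitted
    directly, without cross-validation.
    """
    predictors = list(predictors or [c for c in table.columns if c != response])
    X, parent = _build_design(table, predictors)
    Xv = X.to_numpy(float)
    sd = Xv.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - Xv.mean(axis=0)) / sd
    y = table[response].to_numpy(float)
    yc = y - y.mean()

    single = lambda_grid is not None and len(lambda_grid) == 1 and len(l1_ratio_grid) == 1
    if single:
        model = ElasticNet(
            alpha=lambda_grid[0],
            l1_ratio=l1_ratio_grid[0],
            fit_intercept=False,
            max_iter=500_000,
            tol=1e-10,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, yc)
        chosen = {"l1_ratio": l1_ratio_grid[0], "lambda": lambda_grid[0]}
    else:
        folds = min(k_folds, len(table))
        if folds < k_folds:
            warnings.warn(
                f"reducing cross-validation folds from {k_folds} to {folds}",
                stacklevel=2,
            )
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed & 0x7FFFFFFF)
        model = ElasticNetCV(
            l1_ratio=list(l1_ratio_grid),
            alphas=list(lambda_grid) if lambda_grid is not None else 30,
            cv=cv,
            fit_intercept=False,
            max_iter=50_000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, yc)
        chosen = {"l1_ratio": float(model.l1_ratio_), "lambda": float(model.alpha_)}
    coefs = dict(zip(X.columns, (float(c) for c in model.coef_)))
    selected = {parent[c] for c, v in coefs.items() if v != 0.0}
    return ModelFit(
        method="elastic_net",
        scope=scope,
        coefficients=coefs,
        selected=selected,
        hyperparameters={**chosen, "k_folds": k_folds, "seed": seed},
    )


# ---------------------------------------------------------------------------
# per-RBP transcript-centric models


def per_rbp_transcript_models(
    table: pd.DataFrame,
    predictors: Sequence[str] = tuple(TRANSCRIPT_PREDICTORS),
    alpha: float = 0.05,
    seed: int = 0,
    methods: Sequence[str] = ("multivariate", "stepwise", "elastic_net"),
) -> tuple[dict[str, dict[str, ModelFit]], pd.DataFrame, pd.DataFrame, list[str]]:
    """Fit the transcript-centric models separately for each RBP.

    Returns (fits, significance matrix of -log10(p) for the multivariate
    fits [RBP x feature], per-feature significant/selected fractions, and
    the list of RBPs skipped for having too few pairs).
    """
    predictors = list(predictors)
    fits: dict[str, dict[str, ModelFit]] = {}
    sig_rows, skipped = {}, []
    for rbp, sub in table.groupby("rbp_id", sort=True):
        if len(sub) < len(predictors) + 2:
            skipped.append(str(rbp))
            continue
        per_method: dict[str, ModelFit] = {}
        try:
            if "multivariate" in methods:
                mv = fit_multivariate(sub, "response", predictors, scope=str(rbp))
                per_method["multivariate"] = mv
                sig_rows[rbp] = {
                    f: -np.log10(max(p, 1e-300)) for f, p in mv.feature_p.items()
                }
            if "stepwise" in methods:
                per_method["stepwise"] = fit_stepwise(
                    sub, "response", predictors, alpha_stay=alpha, scope=str(rbp)
                )
            if "elastic_net" in methods:
                per_method["elastic_net"] = fit_elastic_net(
                    sub, "response", predictors, seed=seed, scope=str(rbp)
                )
        except ValueError as exc:  # rank-deficient sub-design etc.
            skipped.append(f"{rbp} ({exc})")
            continue
        fits[str(rbp)] = per_method
    sig_matrix = pd.DataFrame(sig_rows).T.reindex(columns=predictors)
    frac_rows = []
    for feat in predictors:
        row = {"feature": feat}
        if sig_rows:
            row["frac_significant_multivariate"] = float(
                np.mean([v.get(feat, 0.0) > -np.log10(alpha) for v in sig_rows.values()])
            )
        row["frac_retained_stepwise"] = float(
            np.mean([feat in f["stepwise"].selected for f in fits.values()])
        ) if fits and "stepwise" in methods else np.nan
        row["frac_selected_elastic_net"] = float(
            np.mean([feat in f["elastic_net"].selected for f in fits.values()])
        ) if fits and "elastic_net" in methods else np.nan
        frac_rows.append(row)
    return fits, sig_matrix, pd.DataFrame(frac_rows), skipped


def biotype_effect_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median response per transcript biotype per RBP (long format)."""
    out = (
        table.groupby(["rbp_id", "transcript_type"])["response"]
        .median()
        .reset_index()
        .rename(columns={"response": "median_rho"})
    )
    return out
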