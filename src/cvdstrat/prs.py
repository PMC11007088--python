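"""Polygenic risk-score engine.

Scores are additive dosage-times-weight sums over a per-trait weight
panel, with effect-allele reconciliation against the genotype file.
The leave-one-group-out (LOGO) procedure cross-fits weights so that no
sample is ever scored with weights estimated from its own group:

  1. randomly partition samples into k groups;
  2. run a per-variant logistic GWAS in each of the other k-1 groups;
  3. combine them by fixed-effect inverse-variance meta-analysis;
  4. convert meta effect sizes to weights (default: the meta beta for
     variants whose meta p falls below a threshold, else zero — a
     marginal-effect scheme appropriate for linkage-free panels, with
     externally shrunk weight files as a drop-in alternative);
  5. score the held-out group with those weights;
  6. repeat for every group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, WeightPanel

__all__ = [
    "RawScoreVector",
    "GwasResult",
    "compute_prs",
    "normalize_scores",
    "run_gwas",
    "meta_analyze",
    "logo_prs",
]

_BETA_CLAMP = 10.0  # |beta| cap for separated logistic fits


@dataclass
class RawScoreVector:
    scores: np.ndarray
    trait: str
    n_variants_used: int
    n_skipped_absent: int = 0
    n_skipped_mismatch: int = 0

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite PRS values")


@dataclass
class GwasResult:
    """Per-variant marginal logistic association results."""

    table: pd.DataFrame  # columns: variant_id, beta, se, p, flagged

    def __post_init__(self):
        need = {"variant_id", "beta", "se", "p"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"GWAS table lacks {need - set(self.table.columns)}")


def compute_prs(geno: GenotypeMatrix, panel: WeightPanel) -> RawScoreVector:
    """score_i = sum_v dosage_iv * weight_v, dosage counting the panel's
    effect allele.

    When the genotype file codes the panel's *other* allele, the dosage
    is flipped to ``2 - d``.  Panel variants absent from the genotypes
    are skipped and counted; a variant matching neither allele is
    skipped with a mismatch count.  Missing dosages are mean-imputed
    per variant.
    """
    vindex = geno.variant_index()
    geno_alleles = geno.variants.set_index("variant_id")
    scores = np.zeros(geno.n_samples)
    used = absent = mismatch = 0
    col_means = np.nanmean(geno.dosages, axis=0)
    for _, row in panel.table.iterrows():
        vid = row["variant_id"]
        if vid not in vindex.index:
            absent += 1
            continue
        j = int(vindex[vid])
        d = geno.dosages[:, j]
        d = np.where(np.isnan(d), col_means[j], d)
        ea = geno_alleles.loc[vid, "effect_allele"]
        oa = geno_alleles.loc[vid, "other_allele"] if "other_allele" in geno_alleles.columns else None
        if row["effect_allele"] == ea:
            pass
        elif oa is not None and row["effect_allele"] == oa:
            d = 2.0 - d
        else:
            mismatch += 1
            continue
        scores += d * float(row["weight"])
        used += 1
    if used == 0:
        raise ValueError(f"no overlapping variants between genotypes and {panel.trait} panel")
    return RawScoreVector(scores=scores, trait=panel.trait, n_variants_used=used,
                          n_skipped_absent=absent, n_skipped_mismatch=mismatch)


def normalize_scores(raw, method: str = "inverse_normal") -> np.ndarray:
    """Map scores to a normal distribution.

    Default is the rank-based inverse-normal transform with the Blom
    offset, ``Phi^-1((r - 3/8) / (n + 1/4))``; ``method="zscore"``
    standardizes instead.  Rank order is always preserved.
    """
    x = np.asarray(raw.scores if isinstance(raw, RawScoreVector) else raw, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 scores to normalize")
    if np.ptp(x) == 0:
        raise ValueError("constant scores cannot be normalized")
    if method == "zscore":
        return (x - x.mean()) / x.std()
    if method != "inverse_normal":
        raise ValueError(f"unknown normalization method {method!r}")
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 3.0 / 8.0) / (len(x) + 0.25))


def run_gwas(geno: GenotypeMatrix, pheno) -> GwasResult:
    """Per-variant univariate logistic regression of a binary phenotype
    on dosage (Wald beta/SE/p), vectorized across variants.

    A two-parameter Newton-Raphson solver runs all variants in
    parallel; fits drifting into separation are clamped at |beta| = 10,
    flagged, and given the Rao score-test p-value instead of the Wald
    one.  Missing dosages are mean-imputed.
    """
    y = np.asarray(pheno, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has a single class; GWAS not identifiable")
    X = geno.dosages.copy()
    col_means = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_means, np.where(nan_mask)[1])
    n, m = X.shape

    b0 = np.full(m, np.log(y.mean() / (1 - y.mean())))
    b1 = np.zeros(m)
    for _ in range(60):
        eta = b0[None, :] + X * b1[None, :]
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1 - p)
        r = y[:, None] - p
        g0, g1 = r.sum(axis=0), (X * r).sum(axis=0)
        h00, h01, h11 = w.sum(axis=0), (w * X).sum(axis=0), (w * X * X).sum(axis=0)
        det = np.maximum(h00 * h11 - h01 * h01, 1e-12)
        s0 = (h11 * g0 - h01 * g1) / det
        s1 = (h00 * g1 - h01 * g0) / det
        step = np.clip(np.stack([s0, s1]), -5, 5)
        b0 += step[0]
        b1 += step[1]
        b1 = np.clip(b1, -_BETA_CLAMP - 1, _BETA_CLAMP + 1)
        if np.max(np.abs(step)) < 1e-10:
            break

    flagged = np.abs(b1) >= _BETA_CLAMP
    b1 = np.clip(b1, -_BETA_CLAMP, _BETA_CLAMP)
    eta = b0[None, :] + X * b1[None, :]
    p_hat = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = p_hat * (1 - p_hat)
    h00, h01, h11 = w.sum(axis=0), (w * X).sum(axis=0), (w * X * X).sum(axis=0)
    det = np.maximum(h00 * h11 - h01 * h01, 1e-12)
    se = np.sqrt(np.maximum(h00 / det, 1e-300))
    p_wald = 2 * stats.norm.sf(np.abs(b1) / se)

    # Rao score test at beta1 = 0 (null model: intercept only)
    ybar = y.mean()
    u = ((y - ybar)[:, None] * X).sum(axis=0)
    xbar = X.mean(axis=0)
    v = ybar * (1 - ybar) * ((X - xbar) ** 2).sum(axis=0)
    p_score = stats.chi2.sf(np.where(v > 0, u * u / np.maximum(v, 1e-300), 0.0), df=1)
    pvals = np.where(flagged, p_score, p_wald)

    return GwasResult(pd.DataFrame({
        "variant_id": geno.variants["variant_id"].to_numpy(),
        "beta": b1, "se": se, "p": np.clip(pvals, np.nextafter(0, 1), 1.0),
        "flagged": flagged,
    }))


def meta_analyze(results: list[GwasResult]) -> GwasResult:
    """Fixed-effect inverse-variance meta-analysis across aligned result
    sets: beta = sum(beta_k / se_k^2) / sum(1 / se_k^2)."""
    if len(results) < 2:
        raise ValueError("need >= 2 result sets to meta-analyze")
    ids = results[0].table["variant_id"].to_numpy()
    for r in results[1:]:
        if not np.array_equal(r.table["variant_id"].to_numpy(), ids):
            raise ValueError("misaligned variant ids across GWAS results")
    betas = np.stack([r.table["beta"].to_numpy(float) for r in results])
    ses = np.stack([r.table["se"].to_numpy(float) for r in results])
    w = 1.0 / ses ** 2  # infinite se contributes zero weight
    w_sum = w.sum(axis=0)
    beta = (w * betas).sum(axis=0) / w_sum
    se = 1.0 / np.sqrt(w_sum)
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    flagged = np.any(np.stack([r.table.get("flagged", pd.Series(False, index=r.table.index)).to_numpy()
                               for r in results]), axis=0)
    return GwasResult(pd.DataFrame({
        "variant_id": ids, "beta": beta, "se": se,
        "p": np.clip(p, np.nextafter(0, 1), 1.0), "flagged": flagged,
    }))


def _thresholded_weights(meta: GwasResult, p_threshold: float) -> np.ndarray:
    t = meta.table
    return np.where(t["p"].to_numpy() <= p_threshold, t["beta"].to_numpy(float), 0.0)


def logo_prs(geno: GenotypeMatrix, pheno, k: int = 10, p_threshold: float = 1.0,
             seed: int = 0, weighting=None, max_retries: int = 20,
             return_groups: bool = False):
    """Leave-one-group-out cross-fit PRS (see module docstring).

    Every sample's score derives only from weights estimated without
    its group.  ``weighting`` may be a callable ``(GwasResult) ->
    per-variant weights``; the default is p-thresholded meta betas.
    """
    y = np.asarray(pheno, dtype=int)
    n = geno.n_samples
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    groups = None
    for _ in range(max_retries):
        cand = rng.permutation(np.arange(n) % k)
        sizes = [(y[cand == g] == 1).sum() and (y[cand == g] == 0).sum() for g in range(k)]
        if all(s > 0 for s in sizes):
            groups = cand
            break
    if groups is None:
        counts = [int((y[cand == g] == 1).sum()) for g in range(k)]
        raise ValueError(f"some group lacks both phenotype classes after {max_retries} "
                         f"partitions; per-group case counts {counts}")

    if weighting is None:
        def weighting(meta):  # noqa: F811 - default scheme
            return _thresholded_weights(meta, p_threshold)

    dos = geno.dosages
    col_means = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_means[None, :], dos)
    scores = np.empty(n)
    for g in range(k):
        hold = groups == g
        per_group = []
        for other in range(k):
            if other == g:
                continue
            m = groups == other
            per_group.append(run_gwas(geno.take_samples(m), y[m]))
        # with k=2 there is a single training group and nothing to pool
        meta = per_group[0] if len(per_group) == 1 else meta_analyze(per_group)
        w = np.asarray(weighting(meta), dtype=float)
        scores[hold] = dos[hold] @ w
    rsv = RawScoreVector(scores=scores, trait="LOGO", n_variants_used=geno.n_variants)
    return (rsv, groups) if return_groups else rsv
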