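"""Allele-diversity summaries, down-sampling richness, and canonical
redundancy between imputed and sequenced dosage matrices.

Richness comparisons across ancestry cohorts of very different sizes are
biased because allele discovery saturates with sample size; repeated
down-sampling of each cohort to a common size gives comparable expected
unique-allele counts.

The canonical redundancy of the sequenced dosage matrix Y given the imputed
matrix X (Stewart-Love index) is the fraction of Y's total standardized
variance explained by X through the canonical variates.  With all variates
retained it equals the mean over Y columns of the R^2 from regressing each
column on all of X, which serves as the test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CALLED,
    PROTEIN_CODING_CLASS_I,
    PROTEIN_CODING_CLASS_II,
    CohortCalls,
    DosageMatrix,
    allele_frequencies,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Diversity summaries
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    stratum: str
    n_participants: int
    n_alleles: int
    alleles_per_participant: float
    per_gene: pd.DataFrame          # gene, n_alleles, n_per_participant
    class_means: dict               # {"I": mean distinct alleles/gene, "II": ...}
    cumulative: pd.DataFrame        # gene, rank, cumulative_frequency


def diversity_summary(
    calls: CohortCalls, resolution: int = 3, stratum: str | None = None
) -> DiversitySummary:
    """Distinct-allele counts, per-capita ratios and cumulative AF curves.

    Restricted to protein-coding genes.  Cumulative curves sort each gene's
    allele frequencies descending and accumulate, so the curve is
    non-decreasing and reaches 1 for genes carried (and called) in all
    participants.
    """
    sub = calls.stratum(stratum)
    coding = [g for g in sub.genes
              if g in PROTEIN_CODING_CLASS_I + PROTEIN_CODING_CLASS_II]
    freqs = allele_frequencies(sub, resolution, genes=coding)
    n = len(sub)
    per_gene = (
        freqs.groupby("gene")["allele"].nunique().rename("n_alleles").reset_index()
    )
    per_gene["n_per_participant"] = per_gene["n_alleles"] / n
    class_of = lambda g: "I" if g in PROTEIN_CODING_CLASS_I else "II"
    class_means = (
        per_gene.assign(hla_class=per_gene["gene"].map(class_of))
        .groupby("hla_class")["n_alleles"]
        .mean()
        .to_dict()
    )
    cum = freqs.copy()
    cum["rank"] = cum.groupby("gene").cumcount() + 1
    cum["cumulative_frequency"] = cum.groupby("gene")["frequency"].cumsum()
    return DiversitySummary(
        stratum=stratum or "ALL",
        n_participants=n,
        n_alleles=int(freqs["allele"].nunique()),
        alleles_per_participant=float(freqs["allele"].nunique() / n),
        per_gene=per_gene,
        class_means=class_means,
        cumulative=cum[["gene", "allele", "rank", "frequency", "cumulative_frequency"]],
    )


# ---------------------------------------------------------------------------
# Down-sampling richness
# ---------------------------------------------------------------------------


@dataclass
class RichnessResult:
    gene: str
    stratum: str
    subsample_n: int
    n_draws: int
    expected_unique: float
    sd_unique: float


def downsample_richness(
    calls: CohortCalls,
    stratum: str | None,
    subsample_n: int,
    n_draws: int = 10_000,
    seed: int = 0,
    genes: list[str] | None = None,
    resolution: int = 3,
) -> list[RichnessResult]:
    """Expected unique-allele count under participant down-sampling.

    Draws ``n_draws`` subsets of ``subsample_n`` participants without
    replacement and counts distinct called alleles per gene in each draw.
    Seeded and reproducible.
    """
    sub = calls.stratum(stratum)
    participants = np.array(sub.participants, dtype=object)
    if subsample_n > len(participants):
        raise ValueError(
            f"subsample_n {subsample_n} exceeds stratum size {len(participants)}"
        )
    genes = genes or sub.genes
    long = sub.called_alleles_long(resolution)
    long = long[long["gene"].isin(genes)]
    # per gene: participant -> set of allele codes, as index arrays
    rng = np.random.default_rng(seed)
    pid_pos = {p: i for i, p in enumerate(participants)}
    gene_data = {}
    for gene, grp in long.groupby("gene"):
        codes, uniq = pd.factorize(grp["allele"])
        rows = np.fromiter((pid_pos[p] for p in grp["participant_id"]), dtype=int)
        mat = np.zeros((len(participants), len(uniq)), dtype=bool)
        mat[rows, codes] = True
        gene_data[gene] = mat
    results = []
    counts = {g: np.empty(n_draws) for g in gene_data}
    for d in range(n_draws):
        idx = rng.choice(len(participants), size=subsample_n, replace=False)
        for g, mat in gene_data.items():
            counts[g][d] = mat[idx].any(axis=0).sum()
    for g in genes:
        if g not in gene_data:
            continue
        c = counts[g]
        results.append(
            RichnessResult(
                gene=g,
                stratum=stratum or "ALL",
                subsample_n=subsample_n,
                n_draws=n_draws,
                expected_unique=float(c.mean()),
                sd_unique=float(c.std(ddof=0)),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Canonical redundancy
# ---------------------------------------------------------------------------


@dataclass
class RedundancyResult:
    af_threshold: float
    n_x: int
    n_y: int
    redundancy: float
    canonical_correlations: np.ndarray = field(default_factory=lambda: np.array([]))
    flagged: bool = False


def _standardize_full_rank(M: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, list[int], bool]:
    """Drop zero-variance then linearly dependent columns; standardize."""
    sd = M.std(axis=0)
    keep = [i for i in range(M.shape[1]) if sd[i] > 0]
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / M[:, keep].std(axis=0)
    # QR with column pivoting to drop dependent columns
    q, r, piv = _qr_pivot(Z)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if len(diag) else 0
    dropped = len(keep) - rank
    kept = sorted(piv[:rank])
    return Z[:, kept], [keep[i] for i in kept], dropped > 0


def _qr_pivot(Z: np.ndarray):
    from scipy.linalg import qr

    return qr(Z, mode="economic", pivoting=True)


def cca_redundancy(
    X: DosageMatrix | pd.DataFrame,
    Y: DosageMatrix | pd.DataFrame,
    af_threshold: float = 0.0,
) -> RedundancyResult:
    """Total canonical redundancy of sequenced dosages Y given imputed X.

    Columns with allele frequency <= ``af_threshold`` are removed first
    (DosageMatrix inputs only).  Rows with any missing dosage are dropped.
    Zero-variance and linearly dependent columns are dropped with a log
    entry and the result flagged.
    """
    if isinstance(X, DosageMatrix):
        X = X.filter_af(af_threshold).data
    if isinstance(Y, DosageMatrix):
        Y = Y.filter_af(af_threshold).data
    shared = X.index.intersection(Y.index)
    Xm = X.loc[shared].to_numpy(dtype=float)
    Ym = Y.loc[shared].to_numpy(dtype=float)
    ok = ~(np.isnan(Xm).any(axis=1) | np.isnan(Ym).any(axis=1))
    Xm, Ym = Xm[ok], Ym[ok]
    n = Xm.shape[0]
    if n <= Xm.shape[1] + Ym.shape[1]:
        raise ValueError("need more rows than total columns for CCA")
    Zx, keep_x, flag_x = _standardize_full_rank(Xm)
    Zy, keep_y, flag_y = _standardize_full_rank(Ym)
    flagged = flag_x or flag_y or (len(keep_x) < Xm.shape[1]) or (len(keep_y) < Ym.shape[1])
    if flagged:
        logger.info(
            "cca_redundancy dropped rank-deficient columns: X %d->%d, Y %d->%d",
            Xm.shape[1], len(keep_x), Ym.shape[1], len(keep_y),
        )
    qx, _ = np.linalg.qr(Zx - Zx.mean(axis=0))
    qy, _ = np.linalg.qr(Zy - Zy.mean(axis=0))
    u, s, vt = np.linalg.svd(qx.T @ qy)
    rho = np.clip(s, 0, 1)
    # Y-side canonical variates, unit variance
    V = qy @ vt.T
    V = V / V.std(axis=0)
    # structure correlations of standardized Y columns with variates
    loadings = Zy.T @ V / len(Zy)  # p_y x k structure correlations
    per_variate_varexp = (loadings**2).mean(axis=0)  # fraction of Y variance per variate
    redundancy = float(np.sum(rho**2 * per_variate_varexp))
    return RedundancyResult(
        af_threshold=af_threshold,
        n_x=len(keep_x),
        n_y=len(keep_y),
        redundancy=redundancy,
        canonical_correlations=rho,
        flagged=flagged,
    )


def redundancy_grid(
    X: DosageMatrix,
    Y: DosageMatrix,
    thresholds: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.05, 0.10, 0.20),
) -> pd.DataFrame:
    """Redundancy at the usual allele-frequency threshold grid."""
    rows = []
    for t in thresholds:
        try:
            r = cca_redundancy(X, Y, af_threshold=t)
        except ValueError as e:
            logger.info("redundancy at AF>%s skipped: %s", t, e)
            continue
        rows.append(
            {"af_threshold": t, "n_imputed": r.n_x, "n_sequenced": r.n_y,
             "redundancy": r.redundancy, "flagged": r.flagged}
        )
    return pd.DataFrame(rows)
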