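"""Multiallelic asymmetric linkage disequilibrium between pairs of HLA genes.

Classical r^2 is defined for biallelic markers only.  For multiallelic loci
the asymmetric LD statistic W averages conditional LD over the conditioning
gene's allele distribution:

    W_{A/B} = sqrt( [ sum_ij (h_ij - p_i q_j)^2 / q_j ] / (1 - sum_i p_i^2) )

where h_ij are two-locus haplotype frequencies with margins p (gene A) and
q (gene B).  W_{A/B} measures how much of A's allelic variation is explained
by B; it is direction-dependent (W_{A/B} = 1 whenever A is a deterministic
function of B) and reduces to |r| when both genes are biallelic.

Haplotype frequencies are estimated from unphased genotype pairs by a
two-locus EM: only double heterozygotes are phase-ambiguous (two
configurations), and the E-step weights configurations by products of the
current haplotype frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CALLED, CohortCalls, DosageMatrix, truncate_name

logger = logging.getLogger(__name__)

#: Label pooling rare/unsequenced alleles.
DUMMY_ALLELE = "POOLED"


@dataclass
class HaplotypeFreqTable:
    """I x J haplotype frequency matrix for a gene pair, with margins."""

    gene_a: str
    gene_b: str
    alleles_a: list[str]
    alleles_b: list[str]
    h: np.ndarray
    converged: bool = True
    n_iter: int = 0
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.shape != (len(self.alleles_a), len(self.alleles_b)):
            raise ValueError("haplotype matrix shape does not match allele labels")
        if (self.h < -1e-12).any():
            raise ValueError("negative haplotype frequency")
        if abs(self.h.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    @property
    def p(self) -> np.ndarray:
        """Margins of gene A."""
        return self.h.sum(axis=1)

    @property
    def q(self) -> np.ndarray:
        """Margins of gene B."""
        return self.h.sum(axis=0)


@dataclass
class AldResult:
    w_a_given_b: float
    w_b_given_a: float
    defined: bool = True

    @property
    def w_avg(self) -> float:
        return 0.5 * (self.w_a_given_b + self.w_b_given_a)


# ---------------------------------------------------------------------------
# Genotype preparation
# ---------------------------------------------------------------------------


def genotype_labels(
    calls: CohortCalls,
    gene: str,
    resolution: int = 2,
    min_af: float = 0.0,
    pool: bool = True,
) -> pd.DataFrame:
    """Two allele labels per participant at a gene, with rare-allele pooling.

    Alleles with frequency below ``min_af`` and both slots of no-call or
    single-allele genotypes map to the dummy label, so every participant
    contributes exactly two slots.  (Gene-absent participants are excluded:
    zero copies is real information, not a haplotype draw.)
    """
    t = calls.gene_table(gene)
    t = t[t["state"] != "gene_absent"]
    from .core import allele_frequencies

    freqs = allele_frequencies(calls, resolution, genes=[gene])
    common = set(freqs.loc[freqs["frequency"] >= min_af, "allele"])

    def lab(allele: str | None) -> str:
        if allele is None:
            return DUMMY_ALLELE
        a = truncate_name(allele, resolution)
        return a if (not pool or a in common) else DUMMY_ALLELE

    a1 = [lab(a) if s == CALLED else DUMMY_ALLELE for a, s in zip(t["allele1"], t["state"])]
    a2 = [lab(a) if s == CALLED else DUMMY_ALLELE for a, s in zip(t["allele2"], t["state"])]
    return pd.DataFrame({"a1": a1, "a2": a2}, index=t.index)


def pool_rare_alleles(
    calls: CohortCalls, gene: str, resolution: int = 2, min_af: float = 0.01
) -> pd.DataFrame:
    """Relabeled genotypes at ``gene`` with rare alleles pooled into a dummy."""
    return genotype_labels(calls, gene, resolution, min_af=min_af, pool=True)


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation
# ---------------------------------------------------------------------------


def em_haplotype_frequencies(
    pairs: pd.DataFrame,
    gene_a: str = "A",
    gene_b: str = "B",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeFreqTable:
    """Maximum-likelihood two-locus haplotype frequencies via EM.

    ``pairs`` has columns a1, a2, b1, b2: unordered genotypes at two genes.
    Initialization is the product of marginal allele frequencies
    (deterministic, no random restarts); iteration stops when the largest
    frequency update falls below ``tol``.  The observed-data log-likelihood
    is asserted non-decreasing at every step.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one genotype pair")
    alleles_a = sorted(set(pairs["a1"]) | set(pairs["a2"]))
    alleles_b = sorted(set(pairs["b1"]) | set(pairs["b2"]))
    ia = {a: i for i, a in enumerate(alleles_a)}
    ib = {b: j for j, b in enumerate(alleles_b)}
    I, J = len(alleles_a), len(alleles_b)

    # genotype -> weight, aggregated over identical genotypes
    counts: dict[tuple[int, int, int, int], int] = {}
    for a1, a2, b1, b2 in zip(pairs["a1"], pairs["a2"], pairs["b1"], pairs["b2"]):
        k = (*sorted((ia[a1], ia[a2])), *sorted((ib[b1], ib[b2])))
        counts[k] = counts.get(k, 0) + 1
    n = len(pairs)

    # margins for initialization
    pa = np.zeros(I)
    qb = np.zeros(J)
    for (i1, i2, j1, j2), c in counts.items():
        pa[i1] += c
        pa[i2] += c
        qb[j1] += c
        qb[j2] += c
    pa /= pa.sum()
    qb /= qb.sum()
    h = np.outer(pa, qb)

    def loglik(hm: np.ndarray) -> float:
        ll = 0.0
        for (i1, i2, j1, j2), c in counts.items():
            p1 = hm[i1, j1] * hm[i2, j2]
            p2 = hm[i1, j2] * hm[i2, j1]
            lik = p1 if (i1 == i2 or j1 == j2) else p1 + p2
            ll += c * np.log(max(lik, 1e-300))
        return ll

    prev_ll = loglik(h)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros_like(h)
        for (i1, i2, j1, j2), c in counts.items():
            if i1 != i2 and j1 != j2:  # double het: two phase configurations
                p1 = h[i1, j1] * h[i2, j2]
                p2 = h[i1, j2] * h[i2, j1]
                tot = p1 + p2
                w1 = 0.5 if tot <= 0 else p1 / tot
                new[i1, j1] += c * w1
                new[i2, j2] += c * w1
                new[i1, j2] += c * (1 - w1)
                new[i2, j1] += c * (1 - w1)
            else:
                new[i1, j1] += c
                new[i2, j2] += c
        new /= 2 * n
        ll = loglik(new)
        assert ll >= prev_ll - 1e-8, "EM log-likelihood decreased"
        delta = np.abs(new - h).max()
        h = new
        prev_ll = ll
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "EM for %s/%s did not converge after %d iterations", gene_a, gene_b, max_iter
        )
    return HaplotypeFreqTable(
        gene_a, gene_b, alleles_a, alleles_b, h, converged, it, prev_ll
    )


# ---------------------------------------------------------------------------
# Asymmetric LD
# ---------------------------------------------------------------------------


def asymmetric_ld(hf: HaplotypeFreqTable) -> AldResult:
    """Directional W statistics from a haplotype frequency table.

    A monomorphic gene makes the corresponding denominator zero; the result
    is then flagged ``defined=False`` with NaN values rather than letting
    NaNs propagate silently.
    """
    h, p, q = hf.h, hf.p, hf.q
    d = h - np.outer(p, q)
    den_a = 1.0 - np.sum(p**2)
    den_b = 1.0 - np.sum(q**2)
    if den_a <= 0 or den_b <= 0:
        return AldResult(float("nan"), float("nan"), defined=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        wa = np.sqrt(np.nansum(np.where(q > 0, d**2 / q, 0.0)) / den_a)
        wb = np.sqrt(np.nansum(np.where(p[:, None] > 0, d**2 / p[:, None], 0.0)) / den_b)
    return AldResult(float(min(wa, 1.0)), float(min(wb, 1.0)))


def gene_pair_ald(
    calls: CohortCalls,
    gene_a: str,
    gene_b: str,
    resolution: int = 2,
    min_af: float = 0.01,
) -> tuple[AldResult, HaplotypeFreqTable]:
    """Pool rare alleles, estimate haplotypes by EM, compute W for one pair."""
    la = genotype_labels(calls, gene_a, resolution, min_af)
    lb = genotype_labels(calls, gene_b, resolution, min_af)
    shared = la.index.intersection(lb.index)
    pairs = pd.DataFrame(
        {
            "a1": la.loc[shared, "a1"],
            "a2": la.loc[shared, "a2"],
            "b1": lb.loc[shared, "a1"],
            "b2": lb.loc[shared, "a2"],
        }
    )
    hf = em_haplotype_frequencies(pairs, gene_a, gene_b)
    return asymmetric_ld(hf), hf


def ald_matrix(
    calls: CohortCalls,
    genes: list[str] | None = None,
    resolution: int = 2,
    min_af: float = 0.01,
    stratum: str | None = None,
) -> pd.DataFrame:
    """Symmetric gene x gene matrix of averaged W, unit diagonal.

    Gene pairs where either gene has fewer than two post-pooling alleles are
    reported as NaN (flagged missing).
    """
    sub = calls.stratum(stratum)
    genes = genes or sub.genes
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    m = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            res, hf = gene_pair_ald(sub, ga, gb, resolution, min_af)
            val = res.w_avg if res.defined and len(hf.alleles_a) > 1 and len(hf.alleles_b) > 1 else np.nan
            m.loc[ga, gb] = m.loc[gb, ga] = val
    return m


def biallelic_r2(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray) -> float:
    """Squared Pearson correlation of two 0/1/2 dosage vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)
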