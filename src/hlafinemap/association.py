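"""Firth-penalized logistic association scans, fixed-effect meta-analysis,
amino-acid expansion and conditional analyses.

Firth regression maximizes the Jeffreys-penalized log-likelihood
l*(b) = l(b) + 1/2 log det I(b).  The penalty keeps estimates finite under
(quasi-)separation, which is routine for rare HLA alleles in case-control
data, and removes the leading small-sample bias of the MLE.  P-values come
from the penalized likelihood-ratio test against the covariates-only null;
Wald standard errors from the inverse penalized information are reported
alongside.

Ancestry-stratified scans are combined by fixed-effect inverse-variance
meta-analysis with Cochran's Q for between-stratum heterogeneity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ANCESTRIES, CALLED, CohortCalls, DosageMatrix, truncate_name

logger = logging.getLogger(__name__)

GENOME_WIDE = 5e-8
DEFAULT_N_PHENOTYPES = 11
#: Scan significance threshold: genome-wide alpha split across phenotypes.
DEFAULT_ALPHA = GENOME_WIDE / DEFAULT_N_PHENOTYPES

DEFAULT_COVARIATES = ("age", "sex") + tuple(f"PC{i}" for i in range(1, 11))


class FirthConvergenceError(RuntimeError):
    def __init__(self, msg: str, beta: np.ndarray):
        super().__init__(msg)
        self.beta = beta


@dataclass
class FirthFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float  # penalized
    n_iter: int


def firth_logistic_fit(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    max_halvings: int = 10,
    fixed_zero: np.ndarray | None = None,
) -> FirthFit:
    """Fit logistic regression with the Firth (Jeffreys-prior) penalty.

    Newton iterations on the modified score U*(b) = X'(y - pi + h(1/2 - pi)),
    where h are the hat-matrix diagonals of the weighted design; step-halving
    guards against penalized-likelihood decreases.  Convergence is declared
    when the free coefficients' modified score max-norm drops below ``tol``.

    ``fixed_zero`` marks coefficients constrained to zero while the Jeffreys
    penalty is still evaluated on the *full* information matrix — this is the
    restricted fit the penalized likelihood-ratio test needs, so that the
    penalty terms of the null and alternative have matching dimension.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than parameters")
    free = np.ones(k, dtype=bool)
    if fixed_zero is not None:
        free[np.asarray(fixed_zero)] = False
    beta = np.zeros(k)

    def penalized_loglik(b: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        eta = X @ b
        pi = 1.0 / (1.0 + np.exp(-eta))
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        w = pi * (1 - pi)
        info = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf, pi, info
        ll = float(np.sum(y * np.log(pi) + (1 - y) * np.log(1 - pi)) + 0.5 * logdet)
        return ll, pi, info

    ll, pi, info = penalized_loglik(beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = pi * (1 - pi)
        Xw = X * np.sqrt(w)[:, None]
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as e:
            raise FirthConvergenceError(f"singular information: {e}", beta) from e
        h = np.einsum("ij,jk,ik->i", Xw, info_inv, Xw)
        score = X.T @ (y - pi + h * (0.5 - pi))
        if np.max(np.abs(score[free])) < tol:
            break
        step = np.zeros(k)
        step[free] = np.linalg.solve(
            info[np.ix_(free, free)], score[free]
        )
        new_beta = beta + step
        new_ll, new_pi, new_info = penalized_loglik(new_beta)
        halvings = 0
        while new_ll < ll and halvings < max_halvings:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_pi, new_info = penalized_loglik(new_beta)
            halvings += 1
        beta, ll, pi, info = new_beta, new_ll, new_pi, new_info
    else:
        raise FirthConvergenceError(
            f"Firth fit did not converge in {max_iter} iterations", beta
        )
    se = np.full(k, np.nan)
    se[free] = np.sqrt(
        np.diag(np.linalg.inv(info[np.ix_(free, free)]))
    )
    return FirthFit(beta=beta, se=se, loglik=ll, n_iter=n_iter)


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------


def _design(pheno: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(pheno))]
    cols.extend(pheno[c].to_numpy(dtype=float) for c in covariates)
    return np.column_stack(cols)


def scan(
    dosages: DosageMatrix,
    pheno: pd.DataFrame,
    stratum: str | None = None,
    min_cases: int = 50,
    min_mac: int = 1,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-marker Firth association scan within one ancestry stratum.

    ``pheno`` is indexed by participant with columns ``status``, ``ancestry``
    and the covariates.  Strata with fewer than ``min_cases`` cases are
    skipped (empty result, logged), mirroring the minimal-case-count rule;
    markers with minor allele count below ``min_mac`` are skipped.

    Returns one row per tested marker: marker, stratum, beta, se, p, af,
    n_cases, n_controls.
    """
    ph = pheno if stratum is None else pheno[pheno["ancestry"] == stratum]
    ph = ph.loc[ph.index.intersection(dosages.data.index)]
    n_cases = int(ph["status"].sum())
    if n_cases < min_cases:
        logger.info(
            "stratum %s skipped: %d cases < %d", stratum, n_cases, min_cases
        )
        return pd.DataFrame(
            columns=["marker", "stratum", "beta", "se", "p", "af", "n_cases", "n_controls"]
        )
    results = []
    X_base = _design(ph, covariates)
    y_all = ph["status"].to_numpy(dtype=float)
    D = dosages.data.loc[ph.index]
    for marker in dosages.markers:
        d = D[marker].to_numpy(dtype=float)
        ok = ~np.isnan(d)
        y, Xb, dv = y_all[ok], X_base[ok], d[ok]
        ac = dv.sum()
        mac = min(ac, 2 * len(dv) - ac)
        if mac < min_mac or dv.std() == 0:
            continue
        X = np.column_stack([Xb, dv])
        try:
            fit = firth_logistic_fit(y, X)
            # restricted fit: marker coefficient pinned to zero, penalty on
            # the full information (penalized LRT with matching dimension)
            null = firth_logistic_fit(y, X, fixed_zero=np.array([X.shape[1] - 1]))
        except FirthConvergenceError:
            logger.warning("marker %s did not converge in stratum %s", marker, stratum)
            continue
        lrt = max(2.0 * (fit.loglik - null.loglik), 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
        results.append(
            {
                "marker": marker,
                "stratum": stratum if stratum is not None else "ALL",
                "beta": float(fit.beta[-1]),
                "se": float(fit.se[-1]),
                "p": max(p, 1e-300),
                "af": float(dv.mean() / 2.0),
                "n_cases": int(y.sum()),
                "n_controls": int(len(y) - y.sum()),
            }
        )
    return pd.DataFrame(results)


def stratified_scan(
    dosages: DosageMatrix,
    pheno: pd.DataFrame,
    strata: tuple[str, ...] = ANCESTRIES,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`scan` per ancestry and stack the results."""
    parts = [scan(dosages, pheno, stratum=s, **kwargs) for s in strata]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(
            columns=["marker", "stratum", "beta", "se", "p", "af", "n_cases", "n_controls"]
        )
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class MetaResult:
    marker: str
    beta: float
    se: float
    p: float
    direction: str
    q: float
    q_p: float
    k: int
    af: float = float("nan")


def meta_fixed(results: pd.DataFrame, stratum_order: tuple[str, ...] = ANCESTRIES) -> MetaResult:
    """Fixed-effect inverse-variance meta-analysis of one marker.

    ``results`` holds one row per stratum (columns marker, stratum, beta,
    se, af optional).  Returns the precision-weighted estimate, a +/-
    direction string in the fixed stratum order, and Cochran's Q with its
    chi-square (k-1 df) p-value; a single stratum passes through unchanged
    with Q = 0 and Q_p = 1.
    """
    if len(results) == 0:
        raise ValueError("meta-analysis needs at least one stratum")
    order = {s: i for i, s in enumerate(stratum_order)}
    res = results.sort_values("stratum", key=lambda s: s.map(lambda x: order.get(x, 99)))
    b = res["beta"].to_numpy(dtype=float)
    se = res["se"].to_numpy(dtype=float)
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_meta = float(np.sum(w) ** -0.5)
    z = beta / se_meta
    p = float(2 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (b - beta) ** 2))
    k = len(res)
    q_p = float(stats.chi2.sf(q, df=k - 1)) if k > 1 else 1.0
    direction = "".join("+" if x >= 0 else "-" for x in b)
    af = float(np.average(res["af"], weights=res["n_cases"] + res["n_controls"])) \
        if "af" in res and res["af"].notna().all() and "n_cases" in res else float("nan")
    return MetaResult(
        marker=str(res["marker"].iloc[0]),
        beta=beta,
        se=se_meta,
        p=max(p, 1e-300),
        direction=direction,
        q=q,
        q_p=q_p,
        k=k,
        af=af,
    )


def meta_analyze(results: pd.DataFrame, stratum_order: tuple[str, ...] = ANCESTRIES) -> pd.DataFrame:
    """Meta-analyze every marker in a stacked stratified scan result."""
    rows = []
    for marker, grp in results.groupby("marker", sort=True):
        m = meta_fixed(grp, stratum_order)
        rows.append(vars(m))
    return pd.DataFrame(rows)


def or_with_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio with a Wald confidence interval on the log-odds scale."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return (
        float(np.exp(beta)),
        float(np.exp(beta - zcrit * se)),
        float(np.exp(beta + zcrit * se)),
    )


def significance_filter(
    meta: pd.DataFrame,
    n_phenotypes: int = DEFAULT_N_PHENOTYPES,
    het_alpha: float = 0.05,
) -> pd.DataFrame:
    """Markers passing the genome-wide threshold split across phenotypes.

    The retained subset gets a ``heterogeneous`` flag marking Cochran's Q
    p-values below a Bonferroni bound at the realized test count (the
    number of meta-analyzed markers), not a hard-coded constant.
    """
    alpha = GENOME_WIDE / n_phenotypes
    n_tests = len(meta)
    out = meta[meta["p"] < alpha].copy()
    if n_tests:
        out["heterogeneous"] = out["q_p"] < het_alpha / n_tests
    return out


# ---------------------------------------------------------------------------
# Amino-acid expansion
# ---------------------------------------------------------------------------

GAP = "-"


def expand_amino_acids(
    calls: CohortCalls,
    alignment: dict[str, str],
    genes: list[str] | None = None,
) -> DosageMatrix:
    """Residue-level one-vs-rest dosage markers from 2-field calls.

    ``alignment`` maps 2-field allele names to aligned protein sequences of
    equal length per gene.  Alignment columns containing a gap in any allele
    (indel columns) and monomorphic columns are excluded.  Each remaining
    (position, residue) pair becomes a marker ``GENE_pos{i}_{res}`` whose
    dosage counts the participant's allele copies carrying that residue.
    Participants with a called allele missing from the alignment are set
    missing (NaN) across that gene's residue markers.
    """
    by_gene: dict[str, dict[str, str]] = {}
    for name, seq in alignment.items():
        by_gene.setdefault(name.split("*")[0], {})[name] = seq
    genes = genes or sorted(by_gene)

    all_cols = []
    all_meta = []
    for gene in genes:
        seqs = by_gene.get(gene, {})
        if not seqs:
            continue
        lens = {len(s) for s in seqs.values()}
        if len(lens) != 1:
            raise ValueError(f"unequal alignment lengths for {gene}")
        L = lens.pop()
        t = calls.gene_table(gene)
        t = t[t["state"] == CALLED]
        if t.empty:
            continue
        geno = [
            [truncate_name(a, 2) for a in (r.allele1, r.allele2) if a]
            for r in t.itertuples()
        ]
        known = [all(a in seqs for a in g) for g in geno]

        # polymorphic, gap-free columns
        arr = np.array([list(seqs[a]) for a in sorted(seqs)])
        usable = [
            i
            for i in range(L)
            if GAP not in arr[:, i] and len(set(arr[:, i])) > 1
        ]
        if not usable:
            continue
        # residues actually observed among called alleles
        for i in usable:
            residues = sorted({seqs[a][i] for g in geno for a in g if a in seqs})
            if len(residues) < 2:
                continue
            for res in residues:
                marker = f"{gene}_pos{i + 1}_{res}"
                vals = np.full(len(t), np.nan)
                for r, (g, ok) in enumerate(zip(geno, known)):
                    if ok:
                        vals[r] = sum(1 for a in g if seqs[a][i] == res)
                col = pd.Series(vals, index=t.index, name=marker)
                af = float(np.nansum(vals) / (2 * np.sum(~np.isnan(vals))))
                all_cols.append(col)
                all_meta.append(
                    {"marker": marker, "gene": gene, "label": marker,
                     "resolution": 0, "af": af}
                )
    if not all_cols:
        return DosageMatrix(
            pd.DataFrame(index=calls.participants),
            pd.DataFrame(columns=["gene", "label", "resolution", "af"]),
        )
    data = pd.concat(all_cols, axis=1).reindex(calls.participants)
    meta = pd.DataFrame(all_meta).set_index("marker")
    return DosageMatrix(data, meta)


# ---------------------------------------------------------------------------
# Conditional scans
# ---------------------------------------------------------------------------


def conditional_scan(
    dosages: DosageMatrix,
    pheno: pd.DataFrame,
    condition_on: list[str],
    strata: tuple[str, ...] = ANCESTRIES,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    **kwargs,
) -> pd.DataFrame:
    """Scan with conditioning markers' dosages appended to the covariates.

    Tested markers collinear with a conditioning marker (including a marker
    conditioned on itself) are flagged ``undefined`` with NaN estimates.
    Benjamini-Hochberg q-values are appended to the meta-analyzed output.
    """
    missing = [m for m in condition_on if m not in dosages.markers]
    if missing:
        raise ValueError(f"unknown conditioning markers {missing}")
    cond = dosages.data[condition_on]
    pheno_aug = pheno.join(cond, how="inner")
    cond_names = tuple(condition_on)
    tested = [m for m in dosages.markers if m not in condition_on]

    flagged = []
    keep = []
    for m in tested:
        sub = dosages.data[[m] + condition_on].dropna()
        x = sub[m]
        collinear = False
        for c in condition_on:
            r2 = _safe_r2(x, sub[c])
            if r2 > 1 - 1e-10:
                collinear = True
                break
        (flagged if collinear else keep).append(m)

    res = stratified_scan(
        dosages.select(keep),
        pheno_aug,
        strata=strata,
        covariates=covariates + cond_names,
        **kwargs,
    )
    meta = meta_analyze(res) if len(res) else pd.DataFrame(
        columns=["marker", "beta", "se", "p", "direction", "q", "q_p", "k", "af"]
    )
    if len(meta):
        meta["q_value"] = multipletests(meta["p"], method="fdr_bh")[1]
    meta["undefined"] = False
    for m in flagged:
        meta.loc[len(meta)] = {
            "marker": m, "beta": np.nan, "se": np.nan, "p": np.nan,
            "direction": "", "q": np.nan, "q_p": np.nan, "k": 0,
            "af": np.nan, "q_value": np.nan, "undefined": True,
        }
    return meta


def _safe_r2(x: pd.Series, y: pd.Series) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)
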