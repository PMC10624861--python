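"""Heterogeneity of synonymous-variant effects within 2-field HLA haplotypes.

3-field alleles sharing a 2-field name encode the same protein and differ
only by synonymous coding variants.  If synonymous variation were neutral
for a phenotype, all 3-field alleles of a 2-field haplotype should carry
statistically indistinguishable effects; this module tests that via pairwise
Welch-style comparisons of meta-analyzed log-odds estimates, pooling
underpowered partners into a burden (collapsing) marker when needed.

Four scenarios, given a 2-field haplotype with at least one
scan-significant 3-field allele:

1. several significant alleles: each is compared to the lowest-p lead;
2. one significant allele and a single non-significant partner: direct
   pair comparison;
3. one significant allele and multiple non-significant partners: the
   partners are collapsed into a dummy burden allele, the burden is
   re-associated (Firth, same covariates, per-ancestry then meta-analyzed)
   and compared to the lead;
4. several significant and some non-significant alleles: the
   non-significant ones are handled as in 2/3 against the lead.

The comparison threshold is 0.05 divided by the number of pair tests
actually performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ANCESTRIES, DosageMatrix, truncate_name
from .association import (
    DEFAULT_ALPHA,
    DEFAULT_COVARIATES,
    meta_fixed,
    stratified_scan,
)

logger = logging.getLogger(__name__)

OPPOSITE = "opposite_direction"
SAME_DIRECTION = "same_direction_diff_magnitude"
PARTNER_NS = "partner_not_significant"
NOT_HET = "not_heterogeneous"


@dataclass
class HetTestResult:
    two_field: str
    lead: str
    partner: str
    beta_lead: float
    se_lead: float
    beta_partner: float
    se_partner: float
    partner_significant: bool
    stat: float
    p: float
    category: str = NOT_HET


def welch_pair_test(beta1: float, se1: float, beta2: float, se2: float) -> tuple[float, float]:
    """Compare two effect estimates given only (beta, SE) per side.

    stat = (b1 - b2) / sqrt(se1^2 + se2^2), referred to the standard normal
    (the unequal-variance t statistic with the degrees of freedom taken to
    infinity, which is the only option when the per-group sample moments are
    unavailable; at biobank sample sizes the difference is negligible).
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    stat = (beta1 - beta2) / np.hypot(se1, se2)
    p = float(2 * stats.norm.sf(abs(stat)))
    return float(stat), p


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Recover the log-scale SE from a printed OR confidence interval."""
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return float((np.log(upper) - np.log(lower)) / (2 * zcrit))


def collapse_burden(
    dosages: DosageMatrix, alleles: list[str], mode: str = "sum"
) -> pd.Series:
    """Pool several 3-field alleles of one 2-field haplotype into one marker.

    ``sum`` adds the constituent dosages; ``comphet`` caps the sum at 2.
    Within a single gene the per-participant allele count is already capped
    at two, so both modes coincide for same-haplotype pooling.  Alleles must
    share gene and 2-field prefix.
    """
    if len(alleles) < 2:
        raise ValueError("burden collapsing needs at least two alleles")
    prefixes = {truncate_name(a, 2) for a in alleles}
    if len(prefixes) != 1:
        raise ValueError(f"alleles span several 2-field haplotypes: {sorted(prefixes)}")
    s = dosages.data[alleles].sum(axis=1, skipna=False)
    if mode == "comphet":
        s = s.clip(upper=2)
    elif mode != "sum":
        raise ValueError(f"unknown burden mode {mode!r}")
    s.name = f"{prefixes.pop()}:burden"
    return s


def _burden_meta(
    dosages: DosageMatrix,
    pool: list[str],
    pheno: pd.DataFrame,
    strata: tuple[str, ...],
    covariates: tuple[str, ...],
    min_cases: int,
    mode: str = "sum",
):
    """Associate a collapsed burden marker: per-ancestry Firth, then meta."""
    col = collapse_burden(dosages, pool, mode=mode)
    af = float(np.nansum(col) / (2 * col.notna().sum()))
    burden = DosageMatrix(
        col.to_frame(),
        pd.DataFrame(
            {"gene": pool[0].split("*")[0], "label": col.name, "resolution": 3, "af": af},
            index=pd.Index([col.name], name="marker"),
        ),
    )
    res = stratified_scan(
        burden, pheno, strata=strata, covariates=covariates, min_cases=min_cases
    )
    if len(res) == 0:
        return None
    return meta_fixed(res)


def run_heterogeneity_procedure(
    meta3: pd.DataFrame,
    dosages: DosageMatrix,
    pheno: pd.DataFrame,
    alpha_assoc: float = DEFAULT_ALPHA,
    strata: tuple[str, ...] = ANCESTRIES,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    min_cases: int = 50,
    burden_mode: str = "sum",
) -> tuple[list[HetTestResult], float]:
    """Run the four-scenario synonymous-heterogeneity procedure.

    ``meta3`` is a meta-analyzed 3-field scan (columns marker, beta, se, p);
    ``dosages`` the matching 3-field dosage matrix.  Returns the pair-test
    results (categories assigned at the final Bonferroni threshold) and the
    threshold 0.05 / n_pair_tests itself.
    """
    if "marker" in meta3.columns:
        meta3 = meta3.set_index(pd.Index(meta3["marker"].to_numpy()), drop=False)
    markers = [m for m in meta3.index if m in set(dosages.markers)]
    groups: dict[str, list[str]] = {}
    for m in markers:
        groups.setdefault(truncate_name(m, 2), []).append(m)

    results: list[HetTestResult] = []
    for two_field, members in sorted(groups.items()):
        if len(members) < 2:
            continue
        sub = meta3.loc[members]
        sig = sub[sub["p"] < alpha_assoc]
        if len(sig) == 0:
            continue
        # lead: lowest p; ties by larger |beta|, then marker id
        lead_order = sig.assign(absb=sig["beta"].abs()).sort_values(
            ["p", "absb", "marker"], ascending=[True, False, True]
        )
        lead = lead_order.iloc[0]
        nonsig = sub[sub["p"] >= alpha_assoc]

        def pair(partner_row, partner_name, partner_sig):
            stat, p = welch_pair_test(
                float(lead["beta"]), float(lead["se"]),
                float(partner_row["beta"]), float(partner_row["se"]),
            )
            results.append(
                HetTestResult(
                    two_field=two_field,
                    lead=str(lead["marker"]),
                    partner=partner_name,
                    beta_lead=float(lead["beta"]),
                    se_lead=float(lead["se"]),
                    beta_partner=float(partner_row["beta"]),
                    se_partner=float(partner_row["se"]),
                    partner_significant=partner_sig,
                    stat=stat,
                    p=p,
                )
            )

        # scenarios 1/4: other significant alleles vs the lead
        for m, row in sig.iterrows():
            if m != lead["marker"]:
                pair(row, str(m), True)
        # scenarios 2/4: each non-significant partner compared directly
        for m, row in nonsig.iterrows():
            pair(row, str(m), False)
        # scenario 3: several underpowered partners additionally collapsed
        # into a dummy burden allele and re-associated
        if len(nonsig) > 1:
            burden = _burden_meta(
                dosages, list(nonsig.index), pheno, strata, covariates,
                min_cases, mode=burden_mode,
            )
            if burden is None:
                logger.info("burden for %s had no analyzable stratum", two_field)
            else:
                pair(
                    pd.Series({"beta": burden.beta, "se": burden.se}),
                    f"{two_field}:burden",
                    burden.p < alpha_assoc,
                )

    n_tests = len(results)
    threshold = 0.05 / n_tests if n_tests else np.nan
    for r in results:
        if not n_tests or r.p >= threshold:
            r.category = NOT_HET
        elif not r.partner_significant:
            r.category = PARTNER_NS
        elif np.sign(r.beta_lead) != np.sign(r.beta_partner):
            r.category = OPPOSITE
        else:
            r.category = SAME_DIRECTION
    return results, threshold


def het_results_table(results: list[HetTestResult], threshold: float) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    df["threshold"] = threshold
    return df
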