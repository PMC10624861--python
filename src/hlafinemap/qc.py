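"""Coverage-based QC, the DRB3/4/5 copy-assignment heuristic, and cleaning
of imputed calls.

Sequencing-based HLA callers emit candidate alleles for the secondary DRB
genes (HLA-DRB3/4/5) whenever any reads align there, even for participants
who carry no copy of the gene.  Because each DRB1 haplotype carries at most
one of DRB3/4/5, read depth at these genes relative to DRB1 tracks copy
number: roughly equal depth means two copies, half depth means one, and much
less means none.  :func:`assign_drb345` implements that heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core import (
    CALLED,
    GENE_ABSENT,
    NO_CALL,
    CohortCalls,
    truncate_name,
)

logger = logging.getLogger(__name__)

DRB345 = ("HLA-DRB3", "HLA-DRB4", "HLA-DRB5")

#: Genes whose coverage record refers to exon 3 (they lack a second exon).
EXON3_GENES = ("HLA-DRB2", "HLA-DRB8")

UNIMPUTED_SENTINEL = ("99", "01")


@dataclass
class QcConfig:
    """QC thresholds.

    min_reads:
        Minimum mean read count at the diagnostic exon (exon 2; exon 3 for
        DRB2/DRB8) for a call to be retained.  A call with exactly
        ``min_reads`` reads is kept ("fewer than 20 reads" defines poor
        coverage).
    drb345_full_ratio:
        DRB3/4/5 coverage as a fraction of DRB1 coverage above which both
        candidate alleles are assigned (two copies).
    drb345_single_ratio:
        Fraction above which a single copy is assigned.
    dosage_threshold:
        Imputed alleles with dosage below this are dropped (0.8 per the
        imputation provider's documentation; 0.66 liberal, 0.9 strict).
    """

    min_reads: int = 20
    drb345_full_ratio: float = 0.60
    drb345_single_ratio: float = 0.30
    dosage_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.drb345_single_ratio < self.drb345_full_ratio <= 1:
            raise ValueError("need 0 < single_ratio < full_ratio <= 1")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")


def _coverage_lookup(coverage: pd.DataFrame) -> dict:
    return {
        (p, g): r
        for p, g, r in zip(
            coverage["participant_id"], coverage["gene"], coverage["mean_reads"]
        )
    }


def apply_coverage_filter(
    calls: CohortCalls, coverage: pd.DataFrame, cfg: QcConfig | None = None
) -> CohortCalls:
    """Set genotypes with insufficient exonic coverage to ``no_call``.

    ``coverage`` rows are (participant_id, gene, mean_reads), where the
    value refers to exon 2 except for DRB2/DRB8 where it is exon 3.  A
    called genotype without a coverage row is an error naming the missing
    (participant, gene) pairs.
    """
    cfg = cfg or QcConfig()
    cov = _coverage_lookup(coverage)
    df = calls.genotypes.copy()
    called = df["state"] == CALLED
    missing = [
        (p, g)
        for p, g in zip(df.loc[called, "participant_id"], df.loc[called, "gene"])
        if (p, g) not in cov
    ]
    if missing:
        raise ValueError(f"missing coverage rows for {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    reads = pd.Series(
        [cov.get((p, g), 0.0) for p, g in zip(df["participant_id"], df["gene"])],
        index=df.index,
    )
    drop = called & (reads < cfg.min_reads)
    n = int(drop.sum())
    if n:
        logger.info("coverage filter: %d genotypes set to no_call", n)
    df.loc[drop, ["allele1", "allele2"]] = None
    df.loc[drop, "state"] = NO_CALL
    return CohortCalls(df, calls.ancestry)


def assign_drb345(
    candidates: pd.DataFrame,
    coverage: pd.DataFrame,
    cfg: QcConfig | None = None,
) -> pd.DataFrame:
    """Resolve DRB3/4/5 copy number from coverage relative to DRB1.

    Parameters
    ----------
    candidates:
        Long table (participant_id, gene, allele1, allele2) of the caller's
        candidate alleles at HLA-DRB3/4/5; allele order is the caller's
        listing order, and "the first called allele" means ``allele1``.
    coverage:
        Coverage rows including HLA-DRB1 for every participant.

    Rules, per participant and gene g in {DRB3, DRB4, DRB5}:

    * cov(g) >= full_ratio * cov(DRB1) and cov(g) > min_reads
      -> both candidate alleles (two copies);
    * else cov(g) >= single_ratio * cov(DRB1) -> first allele (one copy);
    * else -> gene absent.

    A participant carries at most two secondary DRB copies in total.  If the
    two-allele rule fires for more than one gene, the gene with the highest
    coverage keeps both alleles (ties broken DRB3 < DRB4 < DRB5), the others
    are demoted to the single-allele rule, and assignments past two total
    copies are dropped in the same priority order.

    Returns a genotype table (participant_id, gene, allele1, allele2, state)
    covering all three genes for every participant present in ``coverage``'s
    DRB1 rows.  Participants whose DRB1 failed QC get ``no_call`` at all
    three genes.
    """
    cfg = cfg or QcConfig()
    cov = _coverage_lookup(coverage)
    cand: dict = {}
    for row in candidates.itertuples(index=False):
        alleles = [a for a in (row.allele1, row.allele2) if a and a != "."]
        cand[(row.participant_id, row.gene)] = alleles

    participants = sorted(
        {p for (p, g) in cov if g == "HLA-DRB1"},
        key=str,
    )
    out = []
    for pid in participants:
        drb1 = cov[(pid, "HLA-DRB1")]
        if drb1 < cfg.min_reads or drb1 <= 0:
            for g in DRB345:
                out.append((pid, g, None, None, NO_CALL))
            continue
        two_allele, one_allele = [], []
        for g in DRB345:
            c = cov.get((pid, g), 0.0)
            alleles = cand.get((pid, g), [])
            if not alleles:
                continue
            if c >= cfg.drb345_full_ratio * drb1 and c > cfg.min_reads:
                two_allele.append((g, c))
            elif c >= cfg.drb345_single_ratio * drb1:
                one_allele.append((g, c))
        # order two-allele qualifiers by coverage desc, gene order on ties
        two_allele.sort(key=lambda t: (-t[1], DRB345.index(t[0])))
        assignments: dict[str, list] = {}
        budget = 2
        for i, (g, _) in enumerate(two_allele):
            n = 2 if i == 0 else 1  # demote extra two-allele qualifiers
            n = min(n, budget)
            if n > 0:
                assignments[g] = cand[(pid, g)][:n]
                budget -= n
        one_allele.sort(key=lambda t: (-t[1], DRB345.index(t[0])))
        for g, _ in one_allele:
            if budget > 0:
                assignments[g] = cand[(pid, g)][:1]
                budget -= 1
        for g in DRB345:
            alleles = assignments.get(g, [])
            if alleles:
                a1 = alleles[0]
                a2 = alleles[1] if len(alleles) > 1 else None
                out.append((pid, g, a1, a2, CALLED))
            else:
                out.append((pid, g, None, None, GENE_ABSENT))
    return pd.DataFrame(
        out, columns=["participant_id", "gene", "allele1", "allele2", "state"]
    )


def clean_imputed_calls(
    imputed: pd.DataFrame,
    ancestry: pd.Series,
    cfg: QcConfig | None = None,
) -> CohortCalls:
    """Convert imputed dosage calls into a 2-field genotype cohort.

    ``imputed`` has columns (participant_id, gene, allele, dosage).  Alleles
    whose 2-field name ends in the ``99:01`` unimputed sentinel are removed,
    as are alleles with dosage below ``cfg.dosage_threshold``.  Surviving
    dosages round to copy counts (>= 1.5 -> 2, else 1); more than two copies
    at a gene is an inconsistent-input error.  A (participant, gene) with no
    surviving allele becomes ``no_call``.
    """
    cfg = cfg or QcConfig()
    bad = (imputed["dosage"] < 0) | (imputed["dosage"] > 2)
    if bad.any():
        raise ValueError("imputed dosages must lie in [0, 2]")
    rows = []
    for (pid, gene), grp in imputed.groupby(["participant_id", "gene"], sort=True):
        kept: list[tuple[str, int]] = []
        for allele, dosage in zip(grp["allele"], grp["dosage"]):
            name2 = truncate_name(allele, 2)
            if tuple(name2.split("*")[1].split(":")) == UNIMPUTED_SENTINEL:
                continue
            if dosage < cfg.dosage_threshold:
                continue
            kept.append((name2, 2 if dosage >= 1.5 else 1))
        total = sum(c for _, c in kept)
        if total > 2:
            raise ValueError(
                f"inconsistent imputed input: {total} copies at {gene} "
                f"for participant {pid}"
            )
        if total == 0:
            rows.append((pid, gene, None, None, NO_CALL))
        else:
            alleles: list[str] = []
            for name2, c in kept:
                alleles.extend([name2] * c)
            a1 = alleles[0]
            a2 = alleles[1] if len(alleles) > 1 else None
            rows.append((pid, gene, a1, a2, CALLED))
    df = pd.DataFrame(
        rows, columns=["participant_id", "gene", "allele1", "allele2", "state"]
    )
    return CohortCalls(df, ancestry)
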