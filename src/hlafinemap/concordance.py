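"""Agreement between sequenced and imputed HLA calls.

Concordance for a gene is the number of matching allele copies between the
sequenced and the imputed genotype, summed over participants and divided by
twice the number of participants.  Because imputation reference panels lag
the sequence databases they are compared against, a raw comparison penalizes
the sequencer for calling alleles the imputation panel cannot produce; the
*adjusted* concordance therefore restricts the comparison to sequenced
alleles present in the imputation reference's allele universe.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CALLED, CohortCalls, allele_frequencies, truncate_name


@dataclass
class ConcordanceResult:
    gene: str
    stratum: str | None
    n_participants: int
    n_matches: int
    concordance: float
    adjusted_concordance: float | None = None
    mean_af_mismatch: float | None = None


def match_genotypes(called: Sequence[str], imputed: Sequence[str]) -> int:
    """Number of matching allele copies between two unordered genotypes.

    Maximum multiset intersection, so a homozygote matched against a
    heterozygote sharing one allele scores 1, never 2.
    """
    a, b = Counter(called), Counter(imputed)
    return sum((a & b).values())


def _paired_genotypes(
    calls: CohortCalls, imputed: CohortCalls, gene: str, stratum: str | None
) -> pd.DataFrame:
    """Participants called on both sides for ``gene``, with 2-field alleles."""
    sub = calls.stratum(stratum)
    tc = sub.gene_table(gene)
    ti = imputed.gene_table(gene)
    tc = tc[tc["state"] == CALLED]
    ti = ti[ti["state"] == CALLED]
    shared = tc.index.intersection(ti.index)
    rows = []
    for pid in shared:
        seq = [truncate_name(a, 2) for a in (tc.at[pid, "allele1"], tc.at[pid, "allele2"]) if a]
        imp = [truncate_name(a, 2) for a in (ti.at[pid, "allele1"], ti.at[pid, "allele2"]) if a]
        rows.append((pid, seq, imp))
    return pd.DataFrame(rows, columns=["participant_id", "sequenced", "imputed"])


def gene_concordance(
    calls: CohortCalls,
    imputed: CohortCalls,
    gene: str,
    stratum: str | None = None,
) -> ConcordanceResult:
    """Raw concordance for one gene: sum of matches over 2N allele slots.

    ``mean_af_mismatch`` is the mean individual-specific allele frequency
    (mean sequenced-allele frequency of a participant's two alleles) over
    participants with at least one mismatch.
    """
    pairs = _paired_genotypes(calls, imputed, gene, stratum)
    n = len(pairs)
    if n == 0:
        raise ValueError(f"no participants called on both sides at {gene}")
    matches = np.array(
        [match_genotypes(s, i) for s, i in zip(pairs["sequenced"], pairs["imputed"])]
    )
    freqs = allele_frequencies(calls.stratum(stratum), 2, genes=[gene])
    af = dict(zip(freqs["allele"], freqs["frequency"]))
    mm = pairs.loc[matches < 2, "sequenced"]
    mean_af = (
        float(np.mean([np.mean([af.get(a, 0.0) for a in seq]) for seq in mm]))
        if len(mm)
        else None
    )
    return ConcordanceResult(
        gene=gene,
        stratum=stratum,
        n_participants=n,
        n_matches=int(matches.sum()),
        concordance=float(matches.sum() / (2 * n)),
        mean_af_mismatch=mean_af,
    )


def adjusted_concordance(
    calls: CohortCalls,
    imputed: CohortCalls,
    gene: str,
    reference_alleles: Iterable[str],
    stratum: str | None = None,
) -> float:
    """Concordance counting only sequenced alleles known to the reference.

    Exclusion is allele-wise: each participant contributes as many countable
    slots as they have sequenced alleles inside the reference universe
    (0, 1 or 2), and the match count is the multiset intersection of those
    retained alleles with the full imputed genotype.
    """
    ref = {truncate_name(a, 2) for a in reference_alleles}
    if not ref:
        raise ValueError("empty reference allele set")
    pairs = _paired_genotypes(calls, imputed, gene, stratum)
    num = den = 0
    for seq, imp in zip(pairs["sequenced"], pairs["imputed"]):
        kept = [a for a in seq if a in ref]
        den += len(kept)
        num += match_genotypes(kept, imp)
    if den == 0:
        raise ValueError(f"no sequenced allele at {gene} lies in the reference set")
    return num / den


def concordance_table(
    calls: CohortCalls,
    imputed: CohortCalls,
    reference_alleles: Iterable[str],
    genes: Iterable[str] | None = None,
    strata: Iterable[str | None] = (None,),
) -> pd.DataFrame:
    """Raw + adjusted concordance per gene and stratum (long TSV layout)."""
    genes = list(genes) if genes is not None else sorted(
        set(calls.genes) & set(imputed.genes)
    )
    ref = list(reference_alleles)
    rows = []
    for stratum in strata:
        for gene in genes:
            try:
                res = gene_concordance(calls, imputed, gene, stratum)
                adj = adjusted_concordance(calls, imputed, gene, ref, stratum)
            except ValueError:
                continue
            rows.append(
                {
                    "gene": gene,
                    "ancestry": stratum if stratum is not None else "ALL",
                    "n_participants": res.n_participants,
                    "concordance": res.concordance,
                    "adjusted_concordance": adj,
                    "mean_af_mismatch": res.mean_af_mismatch,
                }
            )
    return pd.DataFrame(rows)


def concordance_by_frequency(
    calls: CohortCalls,
    imputed: CohortCalls,
    gene: str,
    bins: Sequence[float],
    stratum: str | None = None,
) -> pd.DataFrame:
    """Per-allele concordance aggregated by sequenced-allele frequency bin.

    Each sequenced allele copy counts as matched or not under the maximum
    multiset pairing of its genotype; copies are then grouped by the AF bin
    of their allele.  Empty bins are reported with NaN concordance.
    """
    bins = list(bins)
    if sorted(bins) != bins or len(bins) < 2:
        raise ValueError("bin edges must be sorted and define at least one bin")
    pairs = _paired_genotypes(calls, imputed, gene, stratum)
    freqs = allele_frequencies(calls.stratum(stratum), 2, genes=[gene])
    af = dict(zip(freqs["allele"], freqs["frequency"]))
    matched: list[tuple[float, int]] = []
    for seq, imp in zip(pairs["sequenced"], pairs["imputed"]):
        remaining = Counter(imp)
        for a in seq:
            hit = 1 if remaining[a] > 0 else 0
            if hit:
                remaining[a] -= 1
            matched.append((af.get(a, 0.0), hit))
    df = pd.DataFrame(matched, columns=["af", "matched"])
    df["bin"] = pd.cut(df["af"], bins=bins, include_lowest=True)
    out = (
        df.groupby("bin", observed=False)["matched"]
        .agg(n="size", concordance="mean")
        .reset_index()
    )
    out.loc[out["n"] == 0, "concordance"] = np.nan
    return out
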