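"""Core HLA nomenclature, genotype containers, dosage encoding and file I/O.

HLA alleles are named ``GENE*F1:F2[:F3[:F4]][X]`` where the colon-separated
fields encode, from left to right, serological group, protein, synonymous
(coding) variants and non-coding variants, and the optional trailing letter
``X`` in {N,L,S,C,A,Q} marks altered expression.  "Resolution" throughout this
package means the number of leading fields retained: 2-field resolution
distinguishes proteins, 3-field resolution additionally distinguishes
synonymous coding variants.

Field values are kept as zero-padded strings, never integers: IMGT field text
is zero-padded with variable width and ``"01"`` and ``"1"`` must never
collide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------

#: The 31 HLA genes and pseudogenes covered by exome capture of the MHC.
CLASS_I_GENES = (
    "HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "HLA-G",
    "HLA-H", "HLA-J", "HLA-K", "HLA-L", "HLA-V", "HLA-Y",
)
CLASS_II_GENES = (
    "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB",
    "HLA-DPA1", "HLA-DPA2", "HLA-DPB1", "HLA-DQA1", "HLA-DQB1",
    "HLA-DRA", "HLA-DRB1", "HLA-DRB2", "HLA-DRB3", "HLA-DRB4",
    "HLA-DRB5", "HLA-DRB6", "HLA-DRB7", "HLA-DRB8", "HLA-DRB9",
)
GENES = CLASS_I_GENES + CLASS_II_GENES

#: Protein-coding subset (pseudogenes excluded).
PROTEIN_CODING_CLASS_I = ("HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "HLA-G")
PROTEIN_CODING_CLASS_II = (
    "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB", "HLA-DPA1", "HLA-DPB1",
    "HLA-DQA1", "HLA-DQB1", "HLA-DRA", "HLA-DRB1", "HLA-DRB3", "HLA-DRB4",
    "HLA-DRB5",
)

#: Secondary DRB genes: carried on only some DRB1 haplotypes, so a
#: participant can legitimately have zero copies ("gene absent").
ABSENTABLE_GENES = frozenset(
    {"HLA-DRB2", "HLA-DRB3", "HLA-DRB4", "HLA-DRB5",
     "HLA-DRB6", "HLA-DRB7", "HLA-DRB8", "HLA-DRB9"}
)

ANCESTRIES = ("AFR", "AMR", "EAS", "EUR", "SAS")

EXPRESSION_SUFFIXES = "NLSCAQ"

# Genotype states
CALLED = "called"
NO_CALL = "no_call"
GENE_ABSENT = "gene_absent"
STATES = (CALLED, NO_CALL, GENE_ABSENT)


class HlaParseError(ValueError):
    """Raised for malformed allele names or unknown genes."""


_ALLELE_RE = re.compile(
    r"^(?P<gene>[A-Za-z0-9-]+)\*"
    r"(?P<fields>\d{1,4}(?::\d{1,4}){0,3})"
    r"(?P<suffix>[NLSCAQ])?$"
)


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A parsed HLA allele name.

    Attributes
    ----------
    gene:
        Normalized gene symbol with the ``HLA-`` prefix (e.g. ``HLA-DQB1``).
    fields:
        1-4 zero-padded digit strings, most significant first.
    suffix:
        Optional expression suffix letter (N/L/S/C/A/Q) or ``None``.
    """

    gene: str
    fields: tuple[str, ...]
    suffix: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.fields) <= 4:
            raise HlaParseError(f"allele must have 1-4 fields, got {self.fields!r}")
        if self.gene not in GENES:
            raise HlaParseError(f"unknown HLA gene {self.gene!r}")
        if self.suffix is not None and self.suffix not in EXPRESSION_SUFFIXES:
            raise HlaParseError(f"unknown expression suffix {self.suffix!r}")

    @property
    def resolution(self) -> int:
        return len(self.fields)

    @property
    def name(self) -> str:
        return f"{self.gene}*{':'.join(self.fields)}{self.suffix or ''}"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name

    def truncate(self, k: int) -> "HlaAllele":
        """Truncate to the first ``k`` fields.

        The expression suffix is dropped whenever an actual truncation
        occurs (moving from 3- to 2-field resolution removes both the third
        field and any expression-change annotation); truncating to the
        current resolution is the identity.
        """
        if k < 1 or k > len(self.fields):
            raise ValueError(
                f"cannot truncate {self.name} to {k} fields "
                f"({len(self.fields)} available)"
            )
        if k == len(self.fields):
            return self
        return HlaAllele(self.gene, self.fields[:k], None)

    def matches(self, other: "HlaAllele", k: int) -> bool:
        """Equality at resolution ``k`` (suffix ignored)."""
        return (
            self.gene == other.gene
            and self.fields[:k] == other.fields[:k]
            and min(len(self.fields), len(other.fields)) >= k
        )


def parse_allele_name(text: str) -> HlaAllele:
    """Parse an allele name such as ``HLA-A*01:01:01:01`` or ``A*24:09N``.

    The gene token is normalized to its ``HLA-`` prefixed form; a malformed
    string or a gene outside the 31-gene catalog raises :class:`HlaParseError`
    naming the offending token.
    """
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise HlaParseError(f"malformed HLA allele name: {text!r}")
    gene = m.group("gene").upper()
    if not gene.startswith("HLA-"):
        gene = "HLA-" + gene
    if gene not in GENES:
        raise HlaParseError(f"unknown HLA gene {gene!r} in {text!r}")
    return HlaAllele(gene, tuple(m.group("fields").split(":")), m.group("suffix"))


def truncate_resolution(allele: HlaAllele, k: int) -> HlaAllele:
    """Functional alias of :meth:`HlaAllele.truncate`."""
    return allele.truncate(k)


def truncate_name(name: str, k: int) -> str:
    """Truncate an allele name string to ``k`` fields (vectorization helper).

    Matches :meth:`HlaAllele.truncate` semantics: the expression suffix is
    removed only when fields are actually dropped.
    """
    gene, _, rest = name.partition("*")
    fields = rest.split(":")
    if k > len(fields):
        raise ValueError(f"cannot truncate {name} to {k} fields")
    if k == len(fields):
        return name
    return f"{gene}*{':'.join(fields[:k])}"


# ---------------------------------------------------------------------------
# Genotype containers
# ---------------------------------------------------------------------------


@dataclass
class GeneGenotype:
    """Genotype of one participant at one gene: 0-2 alleles plus a state."""

    gene: str
    alleles: tuple[HlaAllele, ...]
    state: str = CALLED

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown genotype state {self.state!r}")
        if any(a.gene != self.gene for a in self.alleles):
            raise ValueError("all alleles must belong to the genotype's gene")
        if self.state == CALLED and not 1 <= len(self.alleles) <= 2:
            raise ValueError("called genotype needs 1 or 2 alleles")
        if self.state != CALLED and self.alleles:
            raise ValueError(f"{self.state} genotype must carry no alleles")
        if self.state == GENE_ABSENT and self.gene not in ABSENTABLE_GENES:
            raise ValueError(f"{self.gene} cannot be gene_absent")


_CALL_COLUMNS = ["participant_id", "gene", "allele1", "allele2", "state"]


class CohortCalls:
    """Per-participant, per-gene HLA genotypes for a cohort.

    Backed by a long-format table with columns ``participant_id, gene,
    allele1, allele2, state`` (allele strings at their native resolution,
    ``None`` for empty slots) plus a per-participant ancestry label.

    ``gene_absent`` (a DRB3/4/5-type gene genuinely not carried) is distinct
    from ``no_call`` (QC failure): absent genes contribute zero dosage while
    no-calls are missing data.
    """

    def __init__(self, genotypes: pd.DataFrame, ancestry: pd.Series):
        df = genotypes.copy()
        missing = set(_CALL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"genotype table missing columns {sorted(missing)}")
        df = df[_CALL_COLUMNS]
        df[["allele1", "allele2"]] = df[["allele1", "allele2"]].where(
            df[["allele1", "allele2"]].notna() & (df[["allele1", "allele2"]] != "."),
            None,
        )
        if df.duplicated(["participant_id", "gene"]).any():
            raise ValueError("duplicate (participant, gene) genotype rows")
        bad = ~df["state"].isin(STATES)
        if bad.any():
            raise ValueError(f"unknown genotype states: {df.loc[bad, 'state'].unique()}")
        self.genotypes = df.reset_index(drop=True)
        ancestry = ancestry.copy()
        ancestry.index.name = "participant_id"
        pids = set(df["participant_id"])
        if pids - set(ancestry.index):
            raise ValueError("ancestry label missing for some participants")
        self.ancestry = ancestry

    # -- basic accessors ---------------------------------------------------

    @property
    def participants(self) -> list:
        return list(self.ancestry.index)

    @property
    def genes(self) -> list[str]:
        return sorted(self.genotypes["gene"].unique())

    def __len__(self) -> int:
        return len(self.ancestry)

    def restrict(self, participants: Sequence) -> "CohortCalls":
        keep = set(participants)
        ordered = [p for p in self.participants if p in keep]
        g = self.genotypes[self.genotypes["participant_id"].isin(keep)]
        return CohortCalls(g, self.ancestry.loc[ordered])

    def stratum(self, ancestry: str | None) -> "CohortCalls":
        """Subset to one ancestry; ``None`` returns the full cohort."""
        if ancestry is None:
            return self
        pids = self.ancestry.index[self.ancestry == ancestry]
        if len(pids) == 0:
            raise ValueError(f"empty ancestry stratum {ancestry!r}")
        return self.restrict(pids)

    def gene_table(self, gene: str) -> pd.DataFrame:
        """Rows for one gene, indexed by participant."""
        t = self.genotypes[self.genotypes["gene"] == gene]
        return t.set_index("participant_id")

    def called_alleles_long(self, resolution: int | None = None) -> pd.DataFrame:
        """One row per called allele copy: participant_id, gene, allele."""
        called = self.genotypes[self.genotypes["state"] == CALLED]
        parts = []
        for col in ("allele1", "allele2"):
            sub = called.loc[called[col].notna(), ["participant_id", "gene", col]]
            parts.append(sub.rename(columns={col: "allele"}))
        long = pd.concat(parts, ignore_index=True)
        if resolution is not None:
            long["allele"] = [truncate_name(a, resolution) for a in long["allele"]]
        return long

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.genotypes.copy()
        out[["allele1", "allele2"]] = out[["allele1", "allele2"]].fillna(".")
        out["ancestry"] = out["participant_id"].map(self.ancestry)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortCalls":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        df = df.replace({"": None})
        if "ancestry" in df.columns:
            anc = df.drop_duplicates("participant_id").set_index("participant_id")["ancestry"]
        else:
            raise ValueError("calls TSV must carry an ancestry column")
        return cls(df[_CALL_COLUMNS], anc)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    calls: CohortCalls,
    resolution: int,
    stratum: str | None = None,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-gene allele counts and frequencies at the requested resolution.

    A gene's denominator is the total number of *called* allele copies at
    that gene in the stratum: no-calls and absent genes do not contribute,
    and a hemizygous-style single-allele call contributes one copy.

    Returns a DataFrame with columns ``gene, allele, count, frequency``
    sorted by gene then descending frequency.
    """
    sub = calls.stratum(stratum)
    long = sub.called_alleles_long(resolution)
    if genes is not None:
        long = long[long["gene"].isin(set(genes))]
    if long.empty:
        return pd.DataFrame(columns=["gene", "allele", "count", "frequency"])
    counts = (
        long.groupby(["gene", "allele"], sort=True).size().rename("count").reset_index()
    )
    totals = counts.groupby("gene")["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    counts = counts.sort_values(
        ["gene", "frequency", "allele"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return counts


# ---------------------------------------------------------------------------
# Dosage matrices
# ---------------------------------------------------------------------------


@dataclass
class DosageMatrix:
    """Participants x markers additive dosage matrix.

    ``data`` holds floats so that missing genotypes (no_call) can be NaN;
    observed entries are exact 0/1/2.  ``meta`` is indexed by marker id with
    columns ``gene, label, resolution, af``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.meta.index):
            raise ValueError("dosage columns and metadata rows disagree")

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    def filter_af(self, min_af: float) -> "DosageMatrix":
        keep = self.meta.index[self.meta["af"] > min_af]
        return DosageMatrix(self.data[list(keep)], self.meta.loc[keep])

    def select(self, markers: Sequence[str]) -> "DosageMatrix":
        return DosageMatrix(self.data[list(markers)], self.meta.loc[list(markers)])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="participant_id")

    def concat(self, other: "DosageMatrix") -> "DosageMatrix":
        data = pd.concat([self.data, other.data], axis=1)
        meta = pd.concat([self.meta, other.meta], axis=0)
        return DosageMatrix(data, meta)


def build_dosage_matrix(
    calls: CohortCalls,
    resolution: int = 3,
    min_af: float = 0.0,
    genes: Iterable[str] | None = None,
) -> DosageMatrix:
    """Additive 0/1/2 encoding of allele carriage at the given resolution.

    One column per allele observed at frequency >= ``min_af`` (computed on
    the same cohort), ordered by (gene, descending frequency) for
    deterministic output.  For each participant: called genes yield exact
    counts, absent genes yield zeros, no-calls yield NaN across the gene's
    columns.
    """
    freqs = allele_frequencies(calls, resolution, genes=genes)
    if min_af > 0:
        freqs = freqs[freqs["frequency"] >= min_af]
    marker_order = [f"{a}" for a in freqs["allele"]]

    long = calls.called_alleles_long(resolution)
    if genes is not None:
        long = long[long["gene"].isin(set(genes))]
    long = long[long["allele"].isin(set(marker_order))]
    counts = (
        long.groupby(["participant_id", "allele"]).size().unstack(fill_value=0)
        if not long.empty
        else pd.DataFrame()
    )
    data = counts.reindex(
        index=calls.participants, columns=marker_order, fill_value=0
    ).astype(float)

    # no_call genes are missing data, not zero dosage
    nc = calls.genotypes[calls.genotypes["state"] == NO_CALL]
    gene_cols = {g: freqs.loc[freqs["gene"] == g, "allele"].tolist() for g in freqs["gene"].unique()}
    for gene, grp in nc.groupby("gene"):
        cols = gene_cols.get(gene, [])
        if cols:
            data.loc[data.index.isin(grp["participant_id"]), cols] = np.nan

    meta = pd.DataFrame(
        {
            "gene": freqs["gene"].values,
            "label": freqs["allele"].values,
            "resolution": resolution,
            "af": freqs["frequency"].values,
        },
        index=pd.Index(marker_order, name="marker"),
    )
    return DosageMatrix(data, meta)


# ---------------------------------------------------------------------------
# Coverage + VCF I/O
# ---------------------------------------------------------------------------


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t")
    need = {"participant_id", "gene", "mean_reads"}
    if not need <= set(cov.columns):
        raise ValueError(f"coverage TSV must have columns {sorted(need)}")
    if (cov["mean_reads"] < 0).any():
        raise ValueError("negative mean_reads in coverage table")
    return cov


def write_vcf(dosages: DosageMatrix, path: str | Path) -> None:
    """Write allele/residue dosage columns as a VCF 4.2 with dummy positions.

    One biallelic record per marker on chr6 at strictly increasing dummy
    positions; GT is derived from the 0/1/2 dosage (``./.`` for missing).
    """
    samples = [str(p) for p in dosages.data.index]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr6>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for pos, marker in enumerate(dosages.markers, start=1):
            col = dosages.data[marker]
            gts = [gt_map.get(v, "./.") if pd.notna(v) else "./." for v in col]
            mid = marker.replace(" ", "_")
            fh.write(f"chr6\t{pos}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
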