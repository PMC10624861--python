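"""Synthetic multi-ancestry HLA cohorts with the statistical structure the
analysis stages assume.

The generator draws, per participant, two multi-gene haplotypes from an
explicit enumerated haplotype pool for their ancestry (a mixture of coupled
"core" haplotypes carrying realistic inter-gene LD and an independence
expansion of the marginal allele frequencies).  Secondary DRB gene carriage
(HLA-DRB3/4/5) is determined by the DRB1 allele of each haplotype, exon
coverage is drawn proportional to gene copy number, imputed calls are
derived from the truth by a frequency-dependent miscall process restricted
to a reference allele universe, and binary phenotypes follow a logistic
model with allele-level effects plus age, sex and PC covariates.

Everything is driven by a single seed; outputs are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    ANCESTRIES,
    CALLED,
    GENE_ABSENT,
    CohortCalls,
    build_dosage_matrix,
    truncate_name,
)

DRB345 = ("HLA-DRB3", "HLA-DRB4", "HLA-DRB5")

# ---------------------------------------------------------------------------
# Default allele universe
# ---------------------------------------------------------------------------

#: 3-field allele pools with baseline marginal frequencies (sum to 1).
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "HLA-A": {
        "HLA-A*01:01:01": 0.22, "HLA-A*01:01:02": 0.06, "HLA-A*02:01:01": 0.28,
        "HLA-A*03:01:01": 0.16, "HLA-A*11:01:01": 0.12, "HLA-A*24:02:01": 0.10,
        "HLA-A*68:01:02": 0.04, "HLA-A*26:01:01": 0.02,
    },
    "HLA-B": {
        "HLA-B*07:02:01": 0.17, "HLA-B*08:01:01": 0.15, "HLA-B*44:02:01": 0.14,
        "HLA-B*15:01:01": 0.13, "HLA-B*40:01:02": 0.12, "HLA-B*57:01:01": 0.10,
        "HLA-B*27:05:02": 0.08, "HLA-B*35:01:01": 0.06, "HLA-B*18:01:01": 0.04,
        "HLA-B*51:01:01": 0.01,
    },
    "HLA-DRB1": {
        "HLA-DRB1*03:01:01": 0.20, "HLA-DRB1*04:01:01": 0.18,
        "HLA-DRB1*07:01:01": 0.17, "HLA-DRB1*15:01:01": 0.16,
        "HLA-DRB1*01:01:01": 0.15, "HLA-DRB1*13:01:01": 0.14,
    },
    "HLA-DQB1": {
        "HLA-DQB1*02:01:01": 0.24, "HLA-DQB1*02:01:08": 0.08,
        "HLA-DQB1*03:02:01": 0.22, "HLA-DQB1*06:02:01": 0.24,
        "HLA-DQB1*05:01:01": 0.22,
    },
}

#: DRB1 protein (2-field) -> secondary DRB gene and allele carried on that
#: haplotype; proteins absent from the map carry no secondary DRB gene.
DEFAULT_CARRIAGE_MAP: dict[str, tuple[str, str]] = {
    "HLA-DRB1*03:01": ("HLA-DRB3", "HLA-DRB3*01:01:02"),
    "HLA-DRB1*13:01": ("HLA-DRB3", "HLA-DRB3*02:02:01"),
    "HLA-DRB1*04:01": ("HLA-DRB4", "HLA-DRB4*01:03:01"),
    "HLA-DRB1*07:01": ("HLA-DRB4", "HLA-DRB4*01:01:01"),
    "HLA-DRB1*15:01": ("HLA-DRB5", "HLA-DRB5*01:01:01"),
}

#: Coupled core haplotypes (strong DR-DQ and some class I LD), with weights
#: renormalized within the core component.
DEFAULT_CORE_HAPLOTYPES: list[tuple[dict[str, str], float]] = [
    ({"HLA-A": "HLA-A*01:01:01", "HLA-B": "HLA-B*08:01:01",
      "HLA-DRB1": "HLA-DRB1*03:01:01", "HLA-DQB1": "HLA-DQB1*02:01:01"}, 0.18),
    ({"HLA-A": "HLA-A*01:01:02", "HLA-B": "HLA-B*08:01:01",
      "HLA-DRB1": "HLA-DRB1*03:01:01", "HLA-DQB1": "HLA-DQB1*02:01:08"}, 0.07),
    ({"HLA-A": "HLA-A*02:01:01", "HLA-B": "HLA-B*44:02:01",
      "HLA-DRB1": "HLA-DRB1*04:01:01", "HLA-DQB1": "HLA-DQB1*03:02:01"}, 0.20),
    ({"HLA-A": "HLA-A*03:01:01", "HLA-B": "HLA-B*07:02:01",
      "HLA-DRB1": "HLA-DRB1*15:01:01", "HLA-DQB1": "HLA-DQB1*06:02:01"}, 0.20),
    ({"HLA-A": "HLA-A*11:01:01", "HLA-B": "HLA-B*35:01:01",
      "HLA-DRB1": "HLA-DRB1*01:01:01", "HLA-DQB1": "HLA-DQB1*05:01:01"}, 0.13),
    ({"HLA-A": "HLA-A*24:02:01", "HLA-B": "HLA-B*15:01:01",
      "HLA-DRB1": "HLA-DRB1*07:01:01", "HLA-DQB1": "HLA-DQB1*02:01:01"}, 0.14),
    ({"HLA-A": "HLA-A*02:01:01", "HLA-B": "HLA-B*57:01:01",
      "HLA-DRB1": "HLA-DRB1*07:01:01", "HLA-DQB1": "HLA-DQB1*02:01:01"}, 0.08),
]


@dataclass
class PhenotypeModel:
    """Logistic phenotype: status ~ Bern(expit(a + X b + covariate terms))."""

    name: str
    intercept: float                       # logit of the baseline prevalence
    effects: dict[str, float] = field(default_factory=dict)  # marker -> beta
    age_beta: float = 0.01
    sex_beta: float = 0.2
    pc1_beta: float = 0.05


@dataclass
class SimConfig:
    """Full generator configuration; see module docstring."""

    seed: int = 0
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "AFR": 700, "AMR": 300, "EAS": 250, "EUR": 3100, "SAS": 650
        }
    )
    marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_MARGINALS.items()}
    )
    core_haplotypes: list[tuple[dict[str, str], float]] = field(
        default_factory=lambda: [(dict(h), w) for h, w in DEFAULT_CORE_HAPLOTYPES]
    )
    core_weight: float = 0.25              # extended (all-gene) haplotype weight
    block_weight: float = 0.35             # DR-DQ-only coupled block weight
    ancestry_tilt: bool = True             # rotate marginal freqs per ancestry
    carriage_map: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_CARRIAGE_MAP)
    )
    # coverage model
    drb1_mean_reads: float = 100.0
    other_mean_reads: float = 80.0
    coverage_log_sd: float = 0.15          # participant-level depth dispersion
    copy_noise_log_sd: float = 0.06        # DRB3/4/5-vs-DRB1 ratio noise (<=10%)
    background_ratio: float = 0.05         # stray coverage at uncarried DRB genes
    # imputation error model: (AF upper bound, miscall probability)
    miscall_bins: tuple[tuple[float, float], ...] = ((0.01, 0.25), (1.01, 0.05))
    unimputed_rate: float = 0.01
    dosage_sd: float = 0.08
    het_dosage_mean: float = 0.95
    hom_dosage_mean: float = 1.90
    reference_excluded: tuple[str, ...] = (
        # 2-field alleles the imputation reference does not know
        "HLA-A*68:01", "HLA-B*51:01",
    )
    phenotypes: list[PhenotypeModel] = field(
        default_factory=lambda: [
            PhenotypeModel(
                name="autoimmune_a",
                intercept=-2.6,
                effects={"HLA-B*27:05:02": 0.8, "HLA-DQB1*02:01:08": 0.5},
            )
        ]
    )
    protein_length: int = 40

    def __post_init__(self) -> None:
        for gene, pool in self.marginals.items():
            if abs(sum(pool.values()) - 1.0) > 1e-9:
                raise ValueError(f"marginal frequencies at {gene} must sum to 1")
        for lo, rate in self.miscall_bins:
            if not 0 <= rate <= 1:
                raise ValueError("miscall rates must lie in [0, 1]")

    @classmethod
    def synonymous_flip(
        cls,
        n: int = 20_000,
        af: float = 0.05,
        beta: float = 0.3,
        seed: int = 0,
        prevalence: float = 0.5,
    ) -> "SimConfig":
        """Single-ancestry scenario where one synonymous variant flips the
        sign of a 2-field haplotype's effect.

        ``HLA-A*01:01:01`` gets +beta and ``HLA-A*01:01:02`` gets -beta,
        each at allele frequency ``af``; the phenotype is balanced
        (prevalence 0.5 by default), the standard design for power
        evaluation.
        """
        marg_a = {
            "HLA-A*01:01:01": af, "HLA-A*01:01:02": af,
            "HLA-A*02:01:01": 0.40, "HLA-A*03:01:01": 0.30,
            "HLA-A*24:02:01": 1.0 - af - af - 0.70,
        }
        marginals = {g: dict(v) for g, v in DEFAULT_MARGINALS.items()}
        marginals["HLA-A"] = marg_a
        pheno = PhenotypeModel(
            name="flip_trait",
            intercept=float(np.log(prevalence / (1 - prevalence))),
            effects={"HLA-A*01:01:01": beta, "HLA-A*01:01:02": -beta},
        )
        return cls(
            seed=seed,
            sample_sizes={"EUR": n},
            marginals=marginals,
            core_haplotypes=[],
            core_weight=0.0,
            ancestry_tilt=False,
            phenotypes=[pheno],
        )


@dataclass
class SimCohort:
    truth: CohortCalls
    coverage: pd.DataFrame            # participant_id, gene, mean_reads
    drb345_candidates: pd.DataFrame   # caller-style candidate alleles
    imputed: pd.DataFrame             # participant_id, gene, allele, dosage
    phenotypes: pd.DataFrame          # index participant; status_<name>, covars
    alignment: dict[str, str]         # 2-field allele -> aligned protein seq
    reference_universe: set[str]      # 2-field alleles known to imputation
    true_copy_number: pd.DataFrame    # participant_id, gene, copies (DRB3/4/5)


# ---------------------------------------------------------------------------
# Haplotype pools
# ---------------------------------------------------------------------------


def _ancestry_marginals(cfg: SimConfig, ancestry: str) -> dict[str, dict[str, float]]:
    """Per-ancestry marginals: the baseline frequency vector rotated by the
    ancestry's index, so each ancestry has the same allele universe but a
    different frequency ranking."""
    if not cfg.ancestry_tilt:
        return {g: dict(v) for g, v in cfg.marginals.items()}
    shift = ANCESTRIES.index(ancestry) if ancestry in ANCESTRIES else 0
    out = {}
    for gene, pool in cfg.marginals.items():
        alleles = list(pool)
        freqs = list(pool.values())
        rotated = freqs[shift % len(freqs):] + freqs[:shift % len(freqs)]
        out[gene] = dict(zip(alleles, rotated))
    return out


def build_haplotype_pool(cfg: SimConfig, ancestry: str) -> tuple[list[dict], np.ndarray]:
    """Explicit enumerated pool: three mixture components.

    1. extended core haplotypes coupling all genes (weight ``core_weight``);
    2. a DR-DQ block drawn jointly from the cores' DRB1-DQB1 pairs with the
       other genes independent (weight ``block_weight``), which makes
       within-class-II LD stronger than class-I/class-II LD;
    3. full independence across genes (remaining weight).
    """
    marg = _ancestry_marginals(cfg, ancestry)
    genes = list(marg)
    haps: dict[tuple, float] = {}

    def add(hap: dict[str, str], w: float) -> None:
        key = tuple(hap[g] for g in genes)
        haps[key] = haps.get(key, 0.0) + w

    def expand(partial: dict[str, str], w: float, free: list[str]) -> None:
        combos = [dict(partial)]
        weights = [w]
        for g in free:
            combos = [dict(c, **{g: a}) for c in combos for a in marg[g]]
            weights = [x * f for x in weights for f in marg[g].values()]
        for c, x in zip(combos, weights):
            add(c, x)

    core_total = sum(w for _, w in cfg.core_haplotypes)
    core_w = cfg.core_weight if core_total > 0 else 0.0
    block_genes = [g for g in ("HLA-DRB1", "HLA-DQB1") if g in genes]
    block_w = cfg.block_weight if (core_total > 0 and len(block_genes) == 2) else 0.0
    if core_w > 0:
        for hap, w in cfg.core_haplotypes:
            add(hap, core_w * w / core_total)
    if block_w > 0:
        for hap, w in cfg.core_haplotypes:
            partial = {g: hap[g] for g in block_genes}
            expand(partial, block_w * w / core_total,
                   [g for g in genes if g not in block_genes])
    indep_w = 1.0 - core_w - block_w
    if indep_w > 0:
        expand({}, indep_w, genes)
    keys = sorted(haps)
    freqs = np.array([haps[k] for k in keys])
    freqs /= freqs.sum()
    pool = [dict(zip(genes, k)) for k in keys]
    return pool, freqs


# ---------------------------------------------------------------------------
# Simulation stages
# ---------------------------------------------------------------------------


def simulate_haplotypes(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw two multi-gene haplotypes per participant.

    Returns (haplotype pairs as a DataFrame of allele names per gene per
    chromosome, ancestry Series).  DRB3/4/5 carriage is attached per
    haplotype from the DRB1 carriage map.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    frames = []
    anc_labels = []
    pid0 = 0
    for ancestry in sorted(cfg.sample_sizes):
        n = cfg.sample_sizes[ancestry]
        pool, freqs = build_haplotype_pool(cfg, ancestry)
        idx = rng.choice(len(pool), size=(n, 2), p=freqs)
        genes = list(pool[0])
        rows = {}
        for c in (0, 1):
            for g in genes:
                rows[f"{g}|{c}"] = [pool[i][g] for i in idx[:, c]]
            # secondary DRB carriage from the DRB1 allele
            if "HLA-DRB1" not in genes:
                continue
            drb1_2f = [truncate_name(pool[i]["HLA-DRB1"], 2) for i in idx[:, c]]
            carried = [cfg.carriage_map.get(a) for a in drb1_2f]
            for g in DRB345:
                rows[f"{g}|{c}"] = [
                    al if (ca is not None and ca[0] == g) else None
                    for ca, al in zip(carried, [c2[1] if c2 else None for c2 in carried])
                ]
        pids = [f"P{pid0 + i:06d}" for i in range(n)]
        pid0 += n
        df = pd.DataFrame(rows, index=pids)
        frames.append(df)
        anc_labels.append(pd.Series(ancestry, index=pids))
    hap = pd.concat(frames)
    ancestry = pd.concat(anc_labels)
    ancestry.index.name = "participant_id"
    return hap, ancestry


def haplotypes_to_calls(hap: pd.DataFrame, ancestry: pd.Series) -> tuple[CohortCalls, pd.DataFrame]:
    """Collapse phased haplotypes into unphased truth genotypes.

    Returns the truth cohort and the DRB3/4/5 true copy-number table.
    """
    genes = sorted({c.split("|")[0] for c in hap.columns})
    pids = hap.index.to_numpy()
    frames = []
    copies_frames = []
    for g in genes:
        a0 = hap[f"{g}|0"].to_numpy(dtype=object)
        a1 = hap[f"{g}|1"].to_numpy(dtype=object)
        has0 = pd.notna(a0)
        has1 = pd.notna(a1)
        n_alleles = has0.astype(int) + has1.astype(int)
        # shift the sole allele into slot 1 when only the second is carried
        first = np.where(has0, a0, a1)
        second = np.where(has0 & has1, a1, None)
        state = np.where(n_alleles > 0, CALLED, GENE_ABSENT)
        df = pd.DataFrame(
            {
                "participant_id": pids,
                "gene": g,
                "allele1": np.where(n_alleles > 0, first, None),
                "allele2": second,
                "state": state,
            }
        )
        if g in DRB345:
            copies_frames.append(
                pd.DataFrame({"participant_id": pids, "gene": g, "copies": n_alleles})
            )
        else:
            df = df[n_alleles > 0]
        frames.append(df)
    calls = CohortCalls(pd.concat(frames, ignore_index=True), ancestry)
    copies = (
        pd.concat(copies_frames, ignore_index=True)
        if copies_frames
        else pd.DataFrame(columns=["participant_id", "gene", "copies"])
    )
    return calls, copies


def simulate_coverage(
    truth: CohortCalls,
    copies: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exon coverage proportional to copy number, plus caller-style DRB3/4/5
    candidate allele lists (two listed alleles per gene with any signal)."""
    pids = truth.participants
    n = len(pids)
    rows = []
    # primary genes: independent depth around their mean
    drb1_cov = cfg.drb1_mean_reads * np.exp(
        rng.normal(0, cfg.coverage_log_sd, size=n)
    )
    for g in [g for g in truth.genes if g not in DRB345]:
        if g == "HLA-DRB1":
            cov = drb1_cov
        else:
            cov = cfg.other_mean_reads * np.exp(
                rng.normal(0, cfg.coverage_log_sd, size=n)
            )
        rows.append(pd.DataFrame(
            {"participant_id": pids, "gene": g, "mean_reads": cov}
        ))
    # secondary DRB genes: ratio to DRB1 tracks copy number
    cmap = copies.pivot(index="participant_id", columns="gene", values="copies")
    cmap = cmap.reindex(pids).fillna(0)
    drb1_series = pd.Series(drb1_cov, index=pids)
    for g in DRB345:
        cc = cmap[g].to_numpy() if g in cmap else np.zeros(n)
        noise = np.exp(rng.normal(0, cfg.copy_noise_log_sd, size=n))
        ratio = np.where(cc > 0, cc / 2.0, cfg.background_ratio)
        cov = drb1_series.to_numpy() * ratio * noise
        rows.append(pd.DataFrame(
            {"participant_id": pids, "gene": g, "mean_reads": cov}
        ))
    coverage = pd.concat(rows, ignore_index=True)

    # candidate alleles: the caller reports two alleles wherever reads align
    cand_rows = []
    for g in DRB345:
        pool = sorted({a for _, a in cfg.carriage_map.values() if a.startswith(g)})
        t = truth.gene_table(g)
        for pid in pids:
            true_alleles = []
            if pid in t.index and t.at[pid, "state"] == CALLED:
                true_alleles = [a for a in (t.at[pid, "allele1"], t.at[pid, "allele2"]) if a]
            if len(true_alleles) == 2:
                cand = true_alleles
            elif len(true_alleles) == 1:
                cand = [true_alleles[0], true_alleles[0]]
            elif pool:
                cand = list(rng.choice(pool, size=2))
            else:
                continue
            cand_rows.append((pid, g, cand[0], cand[1]))
    candidates = pd.DataFrame(
        cand_rows, columns=["participant_id", "gene", "allele1", "allele2"]
    )
    return coverage, candidates


def simulate_imputation(
    truth: CohortCalls,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, set[str]]:
    """Derive imputed 2-field calls with frequency-dependent miscalls.

    Each true allele copy is kept with probability 1 - e(AF); otherwise it
    becomes the unimputed sentinel (with probability ``unimputed_rate``
    overall) or a frequency-weighted different allele from the reference
    universe.  Alleles outside the universe are always miscalled.  Copy
    counts convert to noisy dosages straddling the QC thresholds.
    """
    from .core import allele_frequencies

    freqs = allele_frequencies(truth, 2)
    af = {(g, a): f for g, a, f in zip(freqs["gene"], freqs["allele"], freqs["frequency"])}
    universe: set[str] = {
        a for a in freqs["allele"] if a not in set(cfg.reference_excluded)
    }
    by_gene: dict[str, tuple[list[str], np.ndarray]] = {}
    for g, grp in freqs.groupby("gene"):
        names = [a for a in grp["allele"] if a in universe]
        w = np.array([af[(g, a)] for a in names])
        if len(names):
            by_gene[g] = (names, w / w.sum())

    def miscall_rate(frequency: float) -> float:
        for ub, rate in cfg.miscall_bins:
            if frequency < ub:
                return rate
        return cfg.miscall_bins[-1][1]

    long = truth.called_alleles_long(2)
    long = long[long["gene"].isin(by_gene)]
    out_alleles = []
    u = rng.random(len(long))
    u2 = rng.random(len(long))
    for (pid, gene, allele), keep_u, sent_u in zip(
        long.itertuples(index=False), u, u2
    ):
        in_ref = allele in universe
        e = miscall_rate(af[(gene, allele)])
        if in_ref and keep_u >= e:
            out_alleles.append((pid, gene, allele))
            continue
        if sent_u < cfg.unimputed_rate:
            out_alleles.append((pid, gene, f"{gene}*99:01"))
            continue
        names, w = by_gene[gene]
        choices = [n for n in names if n != allele]
        wts = np.array([wi for n, wi in zip(names, w) if n != allele])
        if not choices:
            out_alleles.append((pid, gene, f"{gene}*99:01"))
            continue
        pick = rng.choice(len(choices), p=wts / wts.sum())
        out_alleles.append((pid, gene, choices[pick]))
    imp = pd.DataFrame(out_alleles, columns=["participant_id", "gene", "allele"])
    counts = (
        imp.groupby(["participant_id", "gene", "allele"]).size().rename("copies").reset_index()
    )
    means = np.where(
        counts["copies"] >= 2, cfg.hom_dosage_mean, cfg.het_dosage_mean
    )
    dos = np.clip(rng.normal(means, cfg.dosage_sd), 0.0, 2.0)
    counts["dosage"] = dos
    return counts[["participant_id", "gene", "allele", "dosage"]], universe


def generate_alignment(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Aligned protein sequences per 2-field allele.

    3-field alleles sharing a 2-field name differ only by synonymous
    variants, hence share one protein sequence: the alignment is keyed by
    2-field name, which enforces that consistency by construction.  Each
    gene gets a random base sequence; each allele mutates a few positions,
    and one position per gene is made an indel column (gap) in one allele to
    exercise indel exclusion.
    """
    amino = np.array(list("ARNDCQEGHILKMFPSTWYV"))
    alignment: dict[str, str] = {}
    gene_alleles: dict[str, set[str]] = {
        g: set(pool) for g, pool in cfg.marginals.items()
    }
    for _, allele in cfg.carriage_map.values():
        gene_alleles.setdefault(allele.split("*")[0], set()).add(allele)
    for gene, pool in sorted(gene_alleles.items()):
        base = rng.choice(amino, size=cfg.protein_length)
        names2 = sorted({truncate_name(a, 2) for a in pool})
        gap_col = int(rng.integers(0, cfg.protein_length))
        for i, name in enumerate(names2):
            seq = base.copy()
            n_mut = int(rng.integers(1, 4))
            pos = rng.choice(cfg.protein_length, size=n_mut, replace=False)
            for p in pos:
                seq[p] = rng.choice(amino)
            if i == len(names2) - 1:
                seq[gap_col] = "-"
            alignment[name] = "".join(seq)
    return alignment


def simulate_phenotypes(
    truth: CohortCalls,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Covariates plus one binary status column per configured phenotype."""
    pids = truth.participants
    n = len(pids)
    age = rng.normal(57, 8, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.normal(0, 1, size=(n, 10))
    anc_shift = {"AFR": 2.0, "AMR": 1.0, "EAS": -1.0, "EUR": 0.0, "SAS": -2.0}
    pcs[:, 0] += truth.ancestry.loc[pids].map(anc_shift).fillna(0).to_numpy()
    pheno = pd.DataFrame(
        {"age": age, "sex": sex, **{f"PC{i+1}": pcs[:, i] for i in range(10)}},
        index=pd.Index(pids, name="participant_id"),
    )
    pheno["ancestry"] = truth.ancestry.loc[pids]

    dosages = build_dosage_matrix(truth, resolution=3)
    for model in cfg.phenotypes:
        missing = [m for m in model.effects if m not in dosages.markers]
        if missing:
            raise ValueError(f"phenotype effects reference unknown markers {missing}")
        eta = np.full(n, model.intercept)
        eta += model.age_beta * (age - 57)
        eta += model.sex_beta * sex
        eta += model.pc1_beta * pcs[:, 0]
        for marker, beta in model.effects.items():
            eta += beta * np.nan_to_num(dosages.data[marker].to_numpy())
        p = 1.0 / (1.0 + np.exp(-eta))
        pheno[f"status_{model.name}"] = (rng.random(n) < p).astype(int)
    return pheno


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Run all generator stages under a single seed."""
    rng = np.random.default_rng(cfg.seed)
    hap, ancestry = simulate_haplotypes(cfg, rng)
    truth, copies = haplotypes_to_calls(hap, ancestry)
    coverage, candidates = simulate_coverage(truth, copies, cfg, rng)
    imputed, universe = simulate_imputation(truth, cfg, rng)
    alignment = generate_alignment(cfg, rng)
    phenotypes = simulate_phenotypes(truth, cfg, rng)
    return SimCohort(
        truth=truth,
        coverage=coverage,
        drb345_candidates=candidates,
        imputed=imputed,
        phenotypes=phenotypes,
        alignment=alignment,
        reference_universe=universe,
        true_copy_number=copies,
    )
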