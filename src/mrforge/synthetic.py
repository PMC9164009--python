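"""Synthetic paired GWAS summary statistics with known causal ground truth.

The generator emulates the data a two-sample MR study consumes: per-SNP
exposure effects gamma_j (standardized continuous trait), outcome effects
theta * gamma_j + alpha_j on the log-odds scale, and sampling noise with
standard errors derived from allele frequency and sample size via
se ~= 1/sqrt(2 * MAF * (1-MAF) * n) for the exposure and the case-control
analogue 1/sqrt(2 * MAF * (1-MAF) * n * K * (1-K)) for the outcome.  The
pleiotropic effects alpha_j implement the classic validity violations:
none, balanced (zero-mean), or directional (non-zero mean), optionally
restricted to a fraction of instruments and optionally correlated with
instrument strength (an InSIDE violation).

Defaults mirror the CRP -> ALS study conditions: exposure GWAS of 204,402,
outcome GWAS of 80,610 with 25.8% cases, and per-SNP exposure effects around
0.05 SD per allele, which puts single-SNP F statistics in the hundreds.

Structural features needed to exercise the QC cascade — palindromic SNPs at
intermediate frequency, confounder-annotated SNPs, LD blocks — are planted
explicitly and recorded in the returned truth record.

Also packages the four-SNP conservative CRP instrument set (the CRP-locus
variants rs3093077, rs1205, rs1130864, rs1800947 with their CRP and ALS
summary statistics) as :func:`table1_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError
from .selection import LDMatrix, TraitAnnotation
from .summary_io import VariantAssociation, write_gwas_summary

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))

#: Trait label attached to planted confounder annotations; a member of the
#: default confounder list used by the selection module.
_CONFOUNDER_TRAIT = "Total cholesterol"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative-model parameters for a paired exposure/outcome GWAS."""

    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_theta: float = 0.0          # causal log-odds per SD exposure
    exposure_beta_scale: float = 0.05  # typical |gamma_j| (SD per allele)
    n_exp: int = 204_402
    n_out: int = 80_610
    case_fraction: float = 20_806 / 80_610
    pleiotropy_mode: str = "none"    # none | balanced | directional
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.01    # used by directional mode
    pleiotropy_fraction: float = 1.0  # fraction of SNPs carrying alpha_j
    inside_violation: bool = False
    n_palindromic_intermediate: int = 0
    n_confounder_annotated: int = 0
    ld_blocks: tuple[tuple[int, float], ...] = ()
    seed: Optional[int] = None

    def __post_init__(self):
        if self.seed is None:
            raise InvalidInputError("SyntheticConfig requires an explicit seed")
        if self.n_snps < 1:
            raise InvalidInputError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidInputError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise InvalidInputError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise InvalidInputError("pleiotropy_fraction must be in [0, 1]")
        if self.n_palindromic_intermediate + self.n_confounder_annotated > self.n_snps:
            raise InvalidInputError(
                "n_palindromic_intermediate + n_confounder_annotated exceeds n_snps; "
                "planted features must not overlap"
            )
        if sum(size for size, _ in self.ld_blocks) > self.n_snps:
            raise InvalidInputError("ld_blocks cover more SNPs than n_snps")
        if not (0 < self.case_fraction < 1):
            raise InvalidInputError("case_fraction must be in (0, 1)")


@dataclass
class SyntheticDataset:
    """Generator output: observable summaries plus the hidden truth record."""

    exposure: list[VariantAssociation]
    outcome: list[VariantAssociation]
    ld: LDMatrix
    annotations: list[TraitAnnotation]
    truth: dict = field(default_factory=dict)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one paired exposure/outcome summary-statistics dataset.

    Deterministic given (config, seed).  The truth record carries theta,
    per-SNP gamma and alpha, and each SNP's intended fate through the QC
    cascade (``palindromic_intermediate``, ``confounder_annotated``).
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_snps
    K = config.case_fraction

    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=L)

    # Planted structural roles: first the intermediate palindromes, then the
    # confounder-annotated SNPs (disjoint by construction).
    pal_idx = np.arange(config.n_palindromic_intermediate)
    conf_idx = np.arange(
        config.n_palindromic_intermediate,
        config.n_palindromic_intermediate + config.n_confounder_annotated,
    )
    # Intermediate palindromes need EAF inside the conventional (0.42, 0.58)
    # exclusion band.
    maf[pal_idx] = rng.uniform(0.43, 0.5, size=len(pal_idx))

    # True per-allele exposure effects: magnitudes spread around the scale,
    # random signs.
    mag = config.exposure_beta_scale * rng.uniform(0.5, 1.5, size=L)
    gamma = mag * rng.choice([-1.0, 1.0], size=L)

    # Pleiotropic (direct) outcome effects.
    alpha = np.zeros(L)
    n_invalid = int(round(config.pleiotropy_fraction * L))
    invalid = np.zeros(L, dtype=bool)
    if config.pleiotropy_mode != "none" and n_invalid > 0:
        invalid[rng.choice(L, size=n_invalid, replace=False)] = True
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        draw = rng.normal(mean, config.pleiotropy_sd, size=n_invalid)
        if config.inside_violation:
            # Couple direct effects to instrument strength, breaking InSIDE.
            draw += 0.5 * config.pleiotropy_mean * (
                np.abs(gamma[invalid]) / np.mean(np.abs(gamma)) - 1.0
            )
        if config.pleiotropy_mode == "directional":
            # Directional pleiotropy is defined on the exposure-increasing
            # orientation: coupling the sign to gamma keeps the Wald-ratio
            # shift one-sided regardless of which allele is labelled as the
            # effect allele.
            draw = np.sign(gamma[invalid]) * draw
        alpha[invalid] = draw

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exp)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_out * K * (1.0 - K))

    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(config.true_theta * gamma + alpha, se_out)
    p_exp = 2 * stats.norm.sf(np.abs(beta_exp / se_exp))
    p_out = 2 * stats.norm.sf(np.abs(beta_out / se_out))

    # Allele assignment and effect-allele frequencies.
    alleles = []
    eaf = np.empty(L)
    for j in range(L):
        if j in set(pal_idx):
            ea, oa = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
            eaf[j] = maf[j] if rng.random() < 0.5 else 1 - maf[j]
        else:
            ea, oa = _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
            eaf[j] = maf[j] if rng.random() < 0.5 else 1 - maf[j]
        alleles.append((ea, oa))

    # Positions: LD-block members sit adjacently within a clumping window;
    # everything else is spaced far apart across chromosomes.
    chrom = np.empty(L, dtype=object)
    pos = np.empty(L, dtype=int)
    r = np.eye(L)
    j = 0
    block_id = 0
    blocks = list(config.ld_blocks)
    spacing = 50_000_000
    for size, corr in blocks:
        for k in range(size):
            chrom[j + k] = str(block_id % 22 + 1)
            pos[j + k] = 1_000_000 + k * 10_000
        idx = np.arange(j, j + size)
        for a in idx:
            for b in idx:
                if a != b:
                    r[a, b] = corr
        j += size
        block_id += 1
    for k in range(j, L):
        chrom[k] = str((block_id + k) % 22 + 1)
        pos[k] = 1_000_000 + ((block_id + k) // 22 + 1) * spacing

    ids = [f"rs{1000 + 7 * j}" for j in range(L)]
    exposure, outcome = [], []
    for j in range(L):
        ea, oa = alleles[j]
        exposure.append(VariantAssociation(
            variant_id=ids[j], effect_allele=ea, other_allele=oa,
            beta=float(beta_exp[j]), se=float(se_exp[j]),
            pvalue=float(max(p_exp[j], 1e-300)), eaf=float(eaf[j]),
            n=config.n_exp, chrom=str(chrom[j]), pos=int(pos[j]),
        ))
        outcome.append(VariantAssociation(
            variant_id=ids[j], effect_allele=ea, other_allele=oa,
            beta=float(beta_out[j]), se=float(se_out[j]),
            pvalue=float(max(p_out[j], 1e-300)), eaf=float(eaf[j]),
            n=config.n_out, chrom=str(chrom[j]), pos=int(pos[j]),
        ))

    annotations = [
        TraitAnnotation(ids[j], _CONFOUNDER_TRAIT, 1e-12) for j in conf_idx
    ]

    truth = {
        "theta": config.true_theta,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "invalid": invalid.tolist(),
        "maf": maf.tolist(),
        "variant_ids": ids,
        "palindromic_intermediate": [ids[j] for j in pal_idx],
        "confounder_annotated": [ids[j] for j in conf_idx],
        "seed": config.seed,
    }
    return SyntheticDataset(
        exposure=exposure,
        outcome=outcome,
        ld=LDMatrix(tuple(ids), r),
        annotations=annotations,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the dataset in the delimited dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": out / "exposure.tsv",
        "outcome": out / "outcome.tsv",
        "ld": out / "ld.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.yaml",
    }
    write_gwas_summary(dataset.exposure, paths["exposure"])
    write_gwas_summary(dataset.outcome, paths["outcome"])
    dataset.ld.write(paths["ld"])
    import pandas as pd

    pd.DataFrame(
        [{"variant_id": a.variant_id, "trait": a.trait_name, "pvalue": a.assoc_pvalue}
         for a in dataset.annotations],
        columns=["variant_id", "trait", "pvalue"],
    ).to_csv(paths["annotations"], sep="\t", index=False)
    import yaml

    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(dataset.truth, fh, sort_keys=True)
    return paths


# The four CRP-locus instruments of the conservative analysis, with their
# exposure (ln CRP per effect allele) and outcome (ALS log-odds) summary
# statistics.  Exposure p-values are not printed with the set; the values
# here are the normal-approximation p from beta/se, which are < 5e-8 for
# all four SNPs.
_TABLE1 = [
    # (rsid, ea, oa, eaf, beta_crp, se_crp, beta_als, se_als, p_als)
    ("rs3093077", "C", "A", 0.0716, 0.21, 0.018, 0.0356, 0.0272, 0.1913),
    ("rs1205",    "C", "T", 0.6899, 0.18, 0.010, -0.0109, 0.0144, 0.4501),
    ("rs1130864", "A", "G", 0.3270, 0.13, 0.008, -0.0296, 0.0146, 0.04302),
    ("rs1800947", "C", "G", 0.9429, 0.26, 0.015, 0.0178, 0.0330, 0.5905),
]


def table1_fixture() -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """The conservative 4-SNP CRP instrument set with its ALS associations."""
    exposure, outcome = [], []
    for rsid, ea, oa, eaf, b_exp, se_exp, b_out, se_out, p_out in _TABLE1:
        z = abs(b_exp / se_exp)
        p_exp = float(2 * stats.norm.sf(z))
        exposure.append(VariantAssociation(
            variant_id=rsid, effect_allele=ea, other_allele=oa,
            beta=b_exp, se=se_exp, pvalue=max(p_exp, 1e-300), eaf=eaf, n=204_402,
        ))
        outcome.append(VariantAssociation(
            variant_id=rsid, effect_allele=ea, other_allele=oa,
            beta=b_out, se=se_out, pvalue=p_out, eaf=eaf, n=80_610,
        ))
    return exposure, outcome
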