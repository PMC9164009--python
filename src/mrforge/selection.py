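"""Instrument QC cascade: LD clumping, weak-instrument and directionality filters.

A valid instrumental variable must be (1) robustly associated with the
exposure, (2) independent of confounders, and (3) act on the outcome only
through the exposure.  This module implements the filters that enforce those
assumptions on summary-level data: greedy LD clumping to near-independence,
the per-SNP F statistic against weak instruments, a local confounder-
annotation filter (a stand-in for PhenoScanner lookups), and Steiger
filtering to drop SNPs whose primary effect is on the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, LDLookupError
from .summary_io import HarmonizedInstrument, VariantAssociation

#: Defaults used throughout: clumping window and r^2 cutoff, weak-instrument
#: F threshold, and genome-wide significance, the standard settings for
#: summary-level MR instrument selection.
DEFAULT_CLUMP_WINDOW_KB = 10_000
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_F_MIN = 10.0
DEFAULT_GWAS_P = 5e-8

#: Traits treated as potential ALS confounders when filtering annotations.
DEFAULT_CONFOUNDER_TRAITS = frozenset(
    {
        "LDL cholesterol",
        "Total cholesterol",
        "Type 2 diabetes",
        "Childhood body mass index",
        "Neutrophil count",
        "White blood cell count",
        "Systolic blood pressure",
        "Diastolic blood pressure",
    }
)

#: Study-level sample sizes used when per-SNP n is absent: the CRP GWAS
#: meta-analysis (204,402 individuals) and the ALS GWAS (20,806 cases +
#: 59,804 controls).
DEFAULT_N_EXPOSURE = 204_402
DEFAULT_N_OUTCOME = 80_610


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise LD correlations (r, not r^2) for a set of variants."""

    variant_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self):
        ids = tuple(self.variant_ids)
        object.__setattr__(self, "variant_ids", ids)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] != len(ids):
            raise InvalidInputError("LD matrix must be square and match variant_ids")
        if not np.allclose(r, r.T, atol=1e-8):
            raise InvalidInputError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise InvalidInputError("LD matrix diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-8):
            raise InvalidInputError("LD correlations must lie in [-1, 1]")
        object.__setattr__(self, "_index", {v: i for i, v in enumerate(ids)})

    def r2(self, id1: str, id2: str) -> float:
        """Squared correlation between two variants; raises if either is absent."""
        idx = self._index
        if id1 not in idx or id2 not in idx:
            missing = id1 if id1 not in idx else id2
            raise LDLookupError(missing)
        return float(self.r[idx[id1], idx[id2]] ** 2)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(tuple(variant_ids), np.eye(len(variant_ids)))

    @classmethod
    def read(cls, path) -> "LDMatrix":
        """Read a delimited square matrix with rsID header row and column."""
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if list(df.index) != list(df.columns):
            raise InvalidInputError(f"{path}: row and column variant IDs differ")
        return cls(tuple(df.columns), df.to_numpy(dtype=float))

    def write(self, path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids).to_csv(path, sep="\t")


@dataclass(frozen=True)
class TraitAnnotation:
    """A reported SNP-trait association from a local annotation table."""

    variant_id: str
    trait_name: str
    assoc_pvalue: float

    def __post_init__(self):
        if not (0 < self.assoc_pvalue <= 1):
            raise InvalidInputError(
                f"{self.variant_id}/{self.trait_name}: p-value must be in (0, 1]"
            )


def read_annotations(path) -> list[TraitAnnotation]:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"variant_id", "trait", "pvalue"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"{path}: annotation table needs columns {sorted(required)}")
    return [
        TraitAnnotation(str(row.variant_id), str(row.trait), float(row.pvalue))
        for row in df.itertuples()
    ]


def clump(
    variants: Sequence[VariantAssociation],
    ld: LDMatrix,
    window_kb: Optional[int] = DEFAULT_CLUMP_WINDOW_KB,
    r2_threshold: float = DEFAULT_CLUMP_R2,
) -> list[VariantAssociation]:
    """Greedy p-value clumping: keep index SNPs, drop their LD partners.

    Repeatedly retains the remaining variant with the smallest p-value and
    discards every other remaining variant within ``window_kb`` whose r^2
    with it exceeds ``r2_threshold``.  ``window_kb=None`` compares all pairs
    regardless of position (positions are then not required).  Ties on
    p-value break by variant ID so the output is deterministic.

    A pair that falls within the window but is absent from ``ld`` raises
    :class:`LDLookupError` — independence is never silently assumed.
    """
    if window_kb is not None:
        for v in variants:
            if v.pos is None:
                raise InvalidInputError(
                    f"{v.variant_id}: position required for windowed clumping"
                )

    def within_window(a: VariantAssociation, b: VariantAssociation) -> bool:
        if window_kb is None:
            return True
        if a.chrom != b.chrom:
            return False
        return abs(a.pos - b.pos) <= window_kb * 1000

    remaining = sorted(variants, key=lambda v: (v.pvalue, v.variant_id))
    retained: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        retained.append(index)
        kept = []
        for v in remaining:
            if within_window(index, v) and ld.r2(index.variant_id, v.variant_id) > r2_threshold:
                continue
            kept.append(v)
        remaining = kept
    return retained


def f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument-strength F statistic, beta^2 / se^2."""
    if not se > 0:
        raise InvalidInputError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def variance_explained(beta: float, maf: float) -> float:
    """Trait variance explained by one SNP: 2 * beta^2 * MAF * (1 - MAF).

    ``beta`` is the per-allele effect on a standardized trait and ``maf`` the
    minor-allele frequency (fold EAF > 0.5 before calling).
    """
    if not (0 <= maf <= 0.5):
        raise InvalidInputError(f"maf must be in [0, 0.5], got {maf}")
    return 2.0 * beta * beta * maf * (1.0 - maf)


def fold_to_maf(eaf: float) -> float:
    """Fold an effect-allele frequency onto the minor-allele side."""
    if not (0 <= eaf <= 1):
        raise InvalidInputError(f"eaf must be in [0, 1], got {eaf}")
    return min(eaf, 1.0 - eaf)


@dataclass
class FilterResult:
    """Retained instruments plus a per-SNP exclusion report."""

    retained: list[HarmonizedInstrument]
    exclusions: pd.DataFrame

    def __iter__(self):
        return iter(self.retained)

    def __len__(self):
        return len(self.retained)


def steiger_filter(
    instruments: Iterable[HarmonizedInstrument],
    n_exp: float = DEFAULT_N_EXPOSURE,
    n_out: float = DEFAULT_N_OUTCOME,
) -> FilterResult:
    """Drop instruments that explain more outcome than exposure variance.

    For each SNP, r^2 with the exposure and with the outcome is computed via
    :func:`variance_explained` from each dataset's own EAF; the causal
    direction is called ``True`` iff r^2_exp > r^2_out (ties excluded).  A
    two-sided Z test on the Fisher-transformed correlations
    ``(atanh r_exp - atanh r_out) / sqrt(1/(n_exp-3) + 1/(n_out-3))`` is
    reported alongside in the exclusion/retention report.

    The outcome-side r^2 applies the same allele-frequency formula to
    log-odds betas — an approximation on the binary scale.
    SNPs with a missing EAF cannot be evaluated and are excluded
    conservatively.
    """
    if n_exp <= 3 or n_out <= 3:
        raise InvalidInputError("sample sizes must exceed 3 for the Steiger Z test")
    retained: list[HarmonizedInstrument] = []
    excl: list[dict] = []
    rows: list[dict] = []
    for ins in instruments:
        if ins.eaf_exp is None or ins.eaf_out is None:
            excl.append({"variant_id": ins.variant_id, "reason": "steiger_unevaluable_missing_eaf"})
            continue
        r2_exp = variance_explained(ins.beta_exp, fold_to_maf(ins.eaf_exp))
        r2_out = variance_explained(ins.beta_out, fold_to_maf(ins.eaf_out))
        direction = r2_exp > r2_out
        z_exp = math.atanh(min(math.sqrt(r2_exp), 1 - 1e-12))
        z_out = math.atanh(min(math.sqrt(r2_out), 1 - 1e-12))
        z_stat = (z_exp - z_out) / math.sqrt(1 / (n_exp - 3) + 1 / (n_out - 3))
        p = 2 * stats.norm.sf(abs(z_stat))
        updated = replace(ins, steiger_direction=direction, r2_exp=r2_exp, r2_out=r2_out)
        rows.append(
            {
                "variant_id": ins.variant_id,
                "r2_exp": r2_exp,
                "r2_out": r2_out,
                "direction": direction,
                "steiger_z": z_stat,
                "steiger_p": p,
            }
        )
        if direction:
            retained.append(updated)
        else:
            excl.append({"variant_id": ins.variant_id, "reason": "steiger_direction_false"})
    report = pd.DataFrame(excl, columns=["variant_id", "reason"])
    result = FilterResult(retained, report)
    result.steiger_table = pd.DataFrame(
        rows, columns=["variant_id", "r2_exp", "r2_out", "direction", "steiger_z", "steiger_p"]
    )
    return result


def confounder_filter(
    instruments: Iterable[HarmonizedInstrument],
    annotations: Iterable[TraitAnnotation],
    confounder_traits: Iterable[str] = DEFAULT_CONFOUNDER_TRAITS,
    p_threshold: float = DEFAULT_GWAS_P,
) -> FilterResult:
    """Exclude instruments annotated to a confounder trait below ``p_threshold``.

    The comparison is strict (p < threshold): an annotation exactly at
    genome-wide significance does not trigger exclusion.
    """
    traits = set(confounder_traits)
    hits: dict[str, list[TraitAnnotation]] = {}
    for ann in annotations:
        if ann.trait_name in traits and ann.assoc_pvalue < p_threshold:
            hits.setdefault(ann.variant_id, []).append(ann)
    retained, excl = [], []
    for ins in instruments:
        if ins.variant_id in hits:
            for ann in hits[ins.variant_id]:
                excl.append(
                    {
                        "variant_id": ins.variant_id,
                        "reason": f"confounder:{ann.trait_name}",
                        "trait": ann.trait_name,
                        "pvalue": ann.assoc_pvalue,
                    }
                )
        else:
            retained.append(ins)
    report = pd.DataFrame(excl, columns=["variant_id", "reason", "trait", "pvalue"])
    return FilterResult(retained, report)


def weak_instrument_filter(
    instruments: Iterable[HarmonizedInstrument],
    f_min: float = DEFAULT_F_MIN,
) -> FilterResult:
    """Drop instruments with exposure F statistic below ``f_min``."""
    retained, excl = [], []
    for ins in instruments:
        f = f_statistic(ins.beta_exp, ins.se_exp)
        updated = replace(ins, f_stat=f)
        if f < f_min:
            excl.append({"variant_id": ins.variant_id, "reason": f"weak_instrument_f={f:.3g}"})
        else:
            retained.append(updated)
    return FilterResult(retained, pd.DataFrame(excl, columns=["variant_id", "reason"]))
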