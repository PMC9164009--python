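"""Reading GWAS summary statistics and harmonizing exposure/outcome effects.

A two-sample Mendelian randomization analysis pairs, for each SNP, the
per-allele effect on the exposure (here: natural-log CRP, mg/L) with the
per-allele effect on the outcome (here: log-odds of ALS).  Both effects must
refer to the *same* effect allele.  GWAS files disagree on which allele they
report, so harmonization aligns the outcome dataset onto the exposure's
effect-allele frame, flipping signs where the alleles are swapped and
resolving strand flips by base complement.

Palindromic SNPs (A/T or C/G) cannot be resolved from alleles alone; when
their allele frequency is near 0.5 not even frequency concordance can settle
the strand, so such "intermediate-frequency" palindromes are excluded.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, InvalidInputError, ParseError

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column names, matching common GWAS-catalog-style exports.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "variant_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "N",
    "chrom": "chrom",
    "pos": "pos",
}

_REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")
_OPTIONAL_FIELDS = ("eaf", "n", "chrom", "pos")


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association summary in a single GWAS.

    ``beta`` is the additive effect per copy of ``effect_allele`` — on the
    exposure scale (per unit ln CRP) or the outcome scale (log-odds of ALS)
    depending on which dataset the record came from.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    n: Optional[float] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self):
        ea, oa = self.effect_allele.upper(), self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in VALID_BASES or oa not in VALID_BASES:
            raise InvalidInputError(
                f"{self.variant_id}: alleles must be single bases A/C/G/T, got {ea}/{oa}"
            )
        if ea == oa:
            raise InvalidInputError(f"{self.variant_id}: effect and other allele are identical")
        if not self.se > 0:
            raise InvalidInputError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise InvalidInputError(f"{self.variant_id}: p-value must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise InvalidInputError(f"{self.variant_id}: eaf must be in [0, 1], got {self.eaf}")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP's exposure and outcome effects expressed for one shared effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None
    palindromic: bool = False
    flipped: bool = False
    steiger_direction: Optional[bool] = None
    f_stat: Optional[float] = None
    r2_exp: Optional[float] = None
    r2_out: Optional[float] = None

    def __post_init__(self):
        if not self.se_exp > 0:
            raise InvalidInputError(f"{self.variant_id}: se_exp must be > 0")
        if not self.se_out > 0:
            raise InvalidInputError(f"{self.variant_id}: se_out must be > 0")


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    a1, a2 = a1.upper(), a2.upper()
    if a1 not in VALID_BASES or a2 not in VALID_BASES:
        raise InvalidInputError(f"alleles must be A/C/G/T, got {a1}/{a2}")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def complement(allele: str) -> str:
    """Watson-Crick complement of a single base."""
    try:
        return _COMPLEMENT[allele.upper()]
    except KeyError:
        raise InvalidInputError(f"allele must be A/C/G/T, got {allele}") from None


def _parse_float(text, what, *, required=True):
    if text is None:
        if required:
            raise ValueError(f"missing {what}")
        return None
    s = str(text).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NONE", "."}:
        if required:
            raise ValueError(f"non-numeric {what}: {text!r}")
        return None
    try:
        value = float(s)
    except ValueError:
        raise ValueError(f"non-numeric {what}: {text!r}") from None
    if math.isnan(value):
        if required:
            raise ValueError(f"non-numeric {what}: {text!r}")
        return None
    return value


def read_gwas_summary(
    path,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[VariantAssociation]:
    """Read a delimited GWAS summary-statistics file.

    The delimiter (tab or comma) is sniffed from the header line.
    ``column_map`` maps the field names ``variant_id, effect_allele,
    other_allele, beta, se, pvalue`` (required) and ``eaf, n, chrom, pos``
    (optional) to the file's actual column headers; unspecified entries fall
    back to :data:`DEFAULT_COLUMNS`.

    Raises :class:`ConfigurationError` if a required column is absent, and
    :class:`ParseError` listing every malformed row (1-based line numbers,
    header = line 1) — bad rows are never silently dropped.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)

    with open(path, "r", newline="") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(f"{path}: empty file (no header)")
        delimiter = "\t" if header_line.count("\t") >= header_line.count(",") else ","
        reader = csv.DictReader(io.StringIO(header_line + fh.read()), delimiter=delimiter)
        header = [h.strip() for h in reader.fieldnames or []]
        for fld in _REQUIRED_FIELDS:
            if cmap[fld] not in header:
                raise ConfigurationError(
                    f"{path}: required column {cmap[fld]!r} (field {fld!r}) not in header {header}"
                )
        have = {fld: (cmap[fld] in header) for fld in _OPTIONAL_FIELDS}

        records: list[VariantAssociation] = []
        row_errors: list[tuple[int, str]] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                chrom = row.get(cmap["chrom"]) if have["chrom"] else None
                pos_raw = _parse_float(row.get(cmap["pos"]), "pos", required=False) if have["pos"] else None
                records.append(
                    VariantAssociation(
                        variant_id=str(row[cmap["variant_id"]]).strip(),
                        effect_allele=str(row[cmap["effect_allele"]]).strip(),
                        other_allele=str(row[cmap["other_allele"]]).strip(),
                        beta=_parse_float(row[cmap["beta"]], "beta"),
                        se=_parse_float(row[cmap["se"]], "se"),
                        pvalue=_parse_float(row[cmap["pvalue"]], "pvalue"),
                        eaf=_parse_float(row.get(cmap["eaf"]), "eaf", required=False) if have["eaf"] else None,
                        n=_parse_float(row.get(cmap["n"]), "n", required=False) if have["n"] else None,
                        chrom=str(chrom).strip() if chrom not in (None, "") else None,
                        pos=int(pos_raw) if pos_raw is not None else None,
                    )
                )
            except (ValueError, InvalidInputError, KeyError) as exc:
                row_errors.append((lineno, str(exc)))
        if row_errors:
            listing = "; ".join(f"line {ln}: {msg}" for ln, msg in row_errors)
            raise ParseError(f"{path}: {len(row_errors)} malformed row(s): {listing}", row_errors)
    return records


def write_gwas_summary(records: Iterable[VariantAssociation], path) -> None:
    """Write records in the same tab-delimited dialect :func:`read_gwas_summary` reads."""
    df = associations_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def associations_to_frame(records: Iterable[VariantAssociation]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "SNP": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pvalue,
                "N": r.n,
                "chrom": r.chrom,
                "pos": r.pos,
            }
        )
    cols = ["SNP", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "N", "chrom", "pos"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class HarmonizationResult:
    """Retained instruments plus a per-SNP exclusion report."""

    instruments: list[HarmonizedInstrument]
    exclusions: pd.DataFrame  # columns: variant_id, reason
    n_shared: int = 0

    def __iter__(self):
        return iter(self.instruments)

    def __len__(self):
        return len(self.instruments)


_EXCL_COLUMNS = ["variant_id", "reason"]


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    intermediate_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizationResult:
    """Align outcome effects onto the exposure's effect-allele frame.

    Rules, applied per exposure SNP:

    * absent from the outcome dataset -> excluded (``missing_in_outcome``);
      no proxy search is attempted;
    * same allele pair, same orientation -> kept as-is;
    * alleles swapped -> outcome beta negated, eaf -> 1 - eaf, ``flipped``;
    * alleles match only after complementing (opposite strand) -> aligned the
      same way on the complemented frame;
    * palindromic pair with exposure EAF strictly inside
      ``intermediate_eaf_band`` -> excluded (``palindromic_intermediate``);
    * palindromic outside the band -> orientation inferred by allele-frequency
      concordance (exposure and outcome EAF on the same side of 0.5); missing
      EAF on either side -> excluded conservatively;
    * any other allele configuration -> excluded (``allele_mismatch``).
    """
    low, high = intermediate_eaf_band
    if not (0 <= low < high <= 1):
        raise InvalidInputError(f"invalid intermediate EAF band {intermediate_eaf_band}")

    out_by_id = {v.variant_id: v for v in outcome}
    instruments: list[HarmonizedInstrument] = []
    excl: list[dict] = []
    n_shared = 0

    for exp in exposure:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            excl.append({"variant_id": exp.variant_id, "reason": "missing_in_outcome"})
            continue
        n_shared += 1
        pal = is_palindromic(exp.effect_allele, exp.other_allele)

        if pal:
            if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
                excl.append({"variant_id": exp.variant_id, "reason": "allele_mismatch"})
                continue
            if exp.eaf is None or out.eaf is None:
                excl.append({"variant_id": exp.variant_id, "reason": "palindromic_missing_eaf"})
                continue
            if low < exp.eaf < high:
                excl.append({"variant_id": exp.variant_id, "reason": "palindromic_intermediate"})
                continue
            # Strand is unresolvable from alleles; align by EAF concordance.
            # The outcome record's nominal allele labels are untrustworthy for
            # palindromes, so frequency alone decides the orientation.
            out_eaf_for_exp_allele = out.eaf if out.effect_allele == exp.effect_allele else 1 - out.eaf
            concordant = (exp.eaf - 0.5) * (out_eaf_for_exp_allele - 0.5) >= 0
            if concordant:
                beta_out, eaf_out, flipped = (
                    (out.beta, out.eaf, False)
                    if out.effect_allele == exp.effect_allele
                    else (-out.beta, 1 - out.eaf, True)
                )
            else:
                beta_out, eaf_out, flipped = (
                    (-out.beta, 1 - out.eaf, True)
                    if out.effect_allele == exp.effect_allele
                    else (out.beta, out.eaf, False)
                )
        else:
            pair_exp = (exp.effect_allele, exp.other_allele)
            pair_out = (out.effect_allele, out.other_allele)
            pair_out_comp = (complement(out.effect_allele), complement(out.other_allele))
            if pair_out == pair_exp or pair_out_comp == pair_exp:
                beta_out, eaf_out, flipped = out.beta, out.eaf, False
            elif pair_out == pair_exp[::-1] or pair_out_comp == pair_exp[::-1]:
                beta_out = -out.beta
                eaf_out = None if out.eaf is None else 1 - out.eaf
                flipped = True
            else:
                excl.append({"variant_id": exp.variant_id, "reason": "allele_mismatch"})
                continue

        instruments.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                palindromic=pal,
                flipped=flipped,
            )
        )

    report = pd.DataFrame(excl, columns=_EXCL_COLUMNS)
    return HarmonizationResult(instruments=instruments, exclusions=report, n_shared=n_shared)


def instruments_to_frame(instruments: Iterable[HarmonizedInstrument]) -> pd.DataFrame:
    rows = []
    for ins in instruments:
        rows.append(
            {
                "variant_id": ins.variant_id,
                "beta_exp": ins.beta_exp,
                "se_exp": ins.se_exp,
                "beta_out": ins.beta_out,
                "se_out": ins.se_out,
                "eaf_exp": ins.eaf_exp,
                "eaf_out": ins.eaf_out,
                "palindromic": ins.palindromic,
                "flipped": ins.flipped,
                "steiger_direction": ins.steiger_direction,
                "f_stat": ins.f_stat,
                "r2_exp": ins.r2_exp,
                "r2_out": ins.r2_out,
            }
        )
    cols = [
        "variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "eaf_out",
        "palindromic", "flipped", "steiger_direction", "f_stat", "r2_exp", "r2_out",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_instruments(instruments: Iterable[HarmonizedInstrument], path) -> None:
    instruments_to_frame(instruments).to_csv(path, sep="\t", index=False)
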