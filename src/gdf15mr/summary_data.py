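"""GWAS summary statistics: data model, delimited-text I/O, and harmonization.

A two-sample Mendelian randomization analysis consumes per-variant association
records from two GWAS — one for the exposure (circulating GDF-15 level, in SD
units) and one for the outcome (gallstone disease, on the log-odds scale).
Before Wald ratios can be formed the two datasets must be *harmonized*: each
instrument's outcome record is located (directly or through a linkage-proxy
substitution), oriented to the exposure's effect allele (flipping the sign of
the outcome beta when the allele labels are swapped, complementing strand when
necessary), and strand-ambiguous palindromic variants with minor-allele
frequency too close to 0.5 are discarded.

The module also embeds the published four-instrument table for GDF-15 and its
gallstone associations in UK Biobank and FinnGen, so the whole summary-level
pipeline runs with no external inputs (see :func:`reference_instruments`).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAssociation",
    "GwasDataset",
    "HarmonizedInstrument",
    "SummaryFormatError",
    "SummaryValidationError",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "kept",
    "write_harmonized",
    "variance_explained",
    "reference_instruments",
    "harmonized_reference",
    "FINNGEN_PROXIES",
    "DEFAULT_COLUMNS",
]


class SummaryFormatError(ValueError):
    """A summary-statistics file does not have the expected layout."""


class SummaryValidationError(ValueError):
    """A summary-statistics record violates a field invariant."""


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"G", "C"})


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record in one GWAS.

    ``beta`` is the additive per-effect-allele estimate: SD units for a
    quantitative exposure, log-odds for a binary outcome.  ``eaf`` may be
    ``None`` when the source GWAS does not report allele frequencies;
    harmonization then relies on allele labels alone.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise SummaryValidationError(
                f"{self.snp_id}: effect and other allele are both {self.effect_allele!r}"
            )
        if not self.se > 0:
            raise SummaryValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise SummaryValidationError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if self.pos <= 0:
            raise SummaryValidationError(f"{self.snp_id}: position must be positive")
        if not 0.0 < self.pvalue <= 1.0:
            raise SummaryValidationError(f"{self.snp_id}: pvalue {self.pvalue} outside (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or G/C variants, whose strand is label-ambiguous."""
        return _is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class GwasDataset:
    """A keyed collection of :class:`VariantAssociation` from one GWAS."""

    trait_label: str
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    sample_size: int | None = None

    @classmethod
    def from_records(
        cls,
        trait_label: str,
        records: Iterable[VariantAssociation],
        sample_size: int | None = None,
    ) -> "GwasDataset":
        out: dict[str, VariantAssociation] = {}
        for rec in records:
            if rec.snp_id in out:
                raise SummaryValidationError(f"duplicate snp_id {rec.snp_id} in {trait_label}")
            out[rec.snp_id] = rec
        return cls(trait_label=trait_label, records=out, sample_size=sample_size)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def get(self, snp_id: str) -> VariantAssociation | None:
        return self.records.get(snp_id)


#: Default column names for delimited summary-statistics files.
DEFAULT_COLUMNS = {
    "snp": "snp",
    "chr": "chr",
    "pos": "pos",
    "ea": "ea",
    "nea": "nea",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p": "p",
}


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
    sample_size: int | None = None,
) -> GwasDataset:
    """Read a delimited-text (TSV or CSV) summary-statistics file.

    Parameters
    ----------
    path
        File with one header row and one row per variant.
    column_map
        Mapping from the canonical keys ``snp, chr, pos, ea, nea, eaf, beta,
        se, p`` to the column names used in the file.  Defaults to the
        canonical names themselves.

    Rows with a missing (empty/NaN) beta or SE are rejected and reported via
    the module logger; a non-positive SE raises with the offending row number.
    Alleles are upper-cased on ingestion.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    delim = _sniff_delimiter(path)

    records: list[VariantAssociation] = []
    rejected: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for key in ("snp", "ea", "nea", "beta", "se", "p"):
            if cols[key] not in header:
                raise SummaryFormatError(
                    f"{path.name}: required column {cols[key]!r} (for {key!r}) not found"
                )
        for i, row in enumerate(reader, start=2):  # header is line 1
            raw_beta = (row.get(cols["beta"]) or "").strip()
            raw_se = (row.get(cols["se"]) or "").strip()
            if raw_beta in ("", "NA", "nan") or raw_se in ("", "NA", "nan"):
                rejected.append((i, "missing beta or se"))
                continue
            se = float(raw_se)
            if not se > 0:
                raise SummaryValidationError(f"{path.name} line {i}: se must be > 0, got {se}")
            raw_eaf = (row.get(cols["eaf"]) or "").strip() if cols["eaf"] in row else ""
            eaf = float(raw_eaf) if raw_eaf not in ("", "NA", "nan") else None
            records.append(
                VariantAssociation(
                    snp_id=row[cols["snp"]].strip(),
                    chrom=str(row.get(cols["chr"], "") or "0").strip(),
                    pos=int(float(row.get(cols["pos"], "") or 1)),
                    effect_allele=row[cols["ea"]].strip().upper(),
                    other_allele=row[cols["nea"]].strip().upper(),
                    eaf=eaf,
                    beta=float(raw_beta),
                    se=se,
                    pvalue=float(row[cols["p"]]),
                )
            )
    for line_no, reason in rejected:
        logger.warning("%s line %d rejected: %s", path.name, line_no, reason)
    return GwasDataset.from_records(trait_label or path.stem, records, sample_size)


def write_summary_stats(dataset: GwasDataset, path: str | Path, delimiter: str = "\t") -> None:
    """Write a dataset back to delimited text with the default column names."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(DEFAULT_COLUMNS.values()))
        for rec in dataset:
            writer.writerow(
                [
                    rec.snp_id,
                    rec.chrom,
                    rec.pos,
                    rec.effect_allele,
                    rec.other_allele,
                    "" if rec.eaf is None else f"{rec.eaf:.10g}",
                    f"{rec.beta:.10g}",
                    f"{rec.se:.10g}",
                    f"{rec.pvalue:.10g}",
                ]
            )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome pair oriented to a common effect allele.

    ``ratio`` is the per-SNP Wald ratio estimate of the causal effect,
    ``beta_outcome / beta_exposure``, with the first-order standard error
    ``se_outcome / |beta_exposure|``.  Dropped records carry no ratio.
    """

    snp_id: str
    status: str  # kept | flipped | dropped_palindromic | dropped_missing | incompatible_alleles
    beta_exposure: float | None = None
    se_exposure: float | None = None
    beta_outcome: float | None = None
    se_outcome: float | None = None
    eaf_exposure: float | None = None
    proxy_of: str | None = None
    ratio: float | None = None
    ratio_se: float | None = None

    @property
    def is_kept(self) -> bool:
        return self.status in ("kept", "flipped")


def _make_kept(
    snp_id: str,
    exp: VariantAssociation,
    beta_out: float,
    se_out: float,
    status: str,
    proxy_of: str | None,
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=snp_id,
        status=status,
        beta_exposure=exp.beta,
        se_exposure=exp.se,
        beta_outcome=beta_out,
        se_outcome=se_out,
        eaf_exposure=exp.eaf,
        proxy_of=proxy_of,
        ratio=beta_out / exp.beta,
        ratio_se=se_out / abs(exp.beta),
    )


def harmonize(
    exposure: GwasDataset,
    outcome: GwasDataset,
    proxy_map: Mapping[str, str] | None = None,
    palindromic_maf_window: float = 0.08,
) -> list[HarmonizedInstrument]:
    """Align an outcome dataset to the exposure's effect alleles.

    For each exposure SNP the outcome record is located by ``snp_id``, or —
    failing that — through ``proxy_map`` (original rsID → proxy rsID), with
    the proxy's statistics used unchanged and recorded via ``proxy_of``.
    Alignment rules:

    * alleles identical → ``kept``;
    * effect/other alleles swapped → negate the outcome beta (and reflect the
      outcome EAF) → ``flipped``;
    * alleles match only after strand complementation → complement, then the
      two rules above apply;
    * palindromic (A/T, G/C) exposure SNPs whose EAF lies inside
      ``[0.5 − w, 0.5 + w]`` are ``dropped_palindromic`` (strand cannot be
      inferred from frequency);
    * no outcome record and no proxy → ``dropped_missing``;
    * irreconcilable allele pairs → ``incompatible_alleles`` (never silent).
    """
    if len(exposure) == 0:
        raise SummaryValidationError("exposure dataset is empty")
    out: list[HarmonizedInstrument] = []
    w = palindromic_maf_window
    for exp in exposure:
        proxy_of: str | None = None
        rec = outcome.get(exp.snp_id)
        if rec is None and proxy_map and exp.snp_id in proxy_map:
            rec = outcome.get(proxy_map[exp.snp_id])
            if rec is not None:
                proxy_of = exp.snp_id
        if rec is None:
            out.append(HarmonizedInstrument(snp_id=exp.snp_id, status="dropped_missing"))
            continue
        if exp.is_palindromic and exp.eaf is not None and 0.5 - w <= exp.eaf <= 0.5 + w:
            out.append(HarmonizedInstrument(snp_id=rec.snp_id, status="dropped_palindromic", proxy_of=proxy_of))
            continue
        if exp.is_palindromic and exp.eaf is None:
            # without a frequency the strand of a palindromic SNP is undecidable
            out.append(HarmonizedInstrument(snp_id=rec.snp_id, status="dropped_palindromic", proxy_of=proxy_of))
            continue

        ea, nea = rec.effect_allele, rec.other_allele
        exp_pair = (exp.effect_allele, exp.other_allele)
        if (ea, nea) == exp_pair:
            out.append(_make_kept(rec.snp_id, exp, rec.beta, rec.se, "kept", proxy_of))
        elif (nea, ea) == exp_pair:
            out.append(_make_kept(rec.snp_id, exp, -rec.beta, rec.se, "flipped", proxy_of))
        else:
            cea = _COMPLEMENT.get(ea)
            cnea = _COMPLEMENT.get(nea)
            if (cea, cnea) == exp_pair:
                out.append(_make_kept(rec.snp_id, exp, rec.beta, rec.se, "kept", proxy_of))
            elif (cnea, cea) == exp_pair:
                out.append(_make_kept(rec.snp_id, exp, -rec.beta, rec.se, "flipped", proxy_of))
            else:
                out.append(
                    HarmonizedInstrument(snp_id=rec.snp_id, status="incompatible_alleles", proxy_of=proxy_of)
                )
    return out


def kept(instruments: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """The subset of instruments usable for estimation (kept or flipped)."""
    return [ins for ins in instruments if ins.is_kept]


def write_harmonized(instruments: Sequence[HarmonizedInstrument], path: str | Path) -> None:
    """Write harmonized instruments as TSV with a ``status`` column."""
    fields = [
        "snp_id", "status", "proxy_of", "beta_exposure", "se_exposure",
        "beta_outcome", "se_outcome", "ratio", "ratio_se",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(fields)
        for ins in instruments:
            writer.writerow(
                ["" if getattr(ins, f) is None else getattr(ins, f) for f in fields]
            )


def variance_explained(exposure: GwasDataset) -> float:
    """Phenotypic variance explained by the instruments, Σⱼ 2pⱼ(1−pⱼ)βⱼ².

    Assumes the exposure is standardized to unit variance; each additive
    per-allele effect β then contributes the variance of its genotype term
    under Hardy–Weinberg equilibrium.
    """
    total = 0.0
    for rec in exposure:
        if rec.eaf is None:
            raise SummaryValidationError(f"{rec.snp_id}: eaf required for variance explained")
        total += 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta**2
    return total


# ---------------------------------------------------------------------------
# Embedded instrument table
# ---------------------------------------------------------------------------
#
# The four genome-wide-significant, LD-independent GDF-15 instruments from a
# 21,758-person GWAS meta-analysis, with their gallstone-disease associations
# in UK Biobank (10,520 cases / 350,674 controls) and FinnGen R5 (19,023 /
# 195,144), as published.  rs112253475 was unavailable in FinnGen and is
# proxied there by rs118170439 (r² = 0.8); the proxy's statistics are used
# unchanged and the original SNP's alleles/EAF are carried over, since the
# source table reports the proxy in the original's row.

_EXPOSURE_ROWS = [
    # snp_id, chrom, pos (hg19), ea, nea, eaf, beta, se, p
    ("rs2517481", "6", 31043931, "G", "C", 0.59, 0.059, 0.010, 1.7e-08),
    ("rs1227734", "19", 18501034, "T", "C", 0.14, 0.370, 0.013, 9.9e-177),
    ("rs60164552", "19", 18488285, "G", "C", 0.92, 0.160, 0.017, 7.9e-22),
    ("rs112253475", "19", 18841757, "A", "G", 0.98, 0.270, 0.044, 6.5e-10),
]

_UKB_OUTCOME_ROWS = [
    ("rs2517481", "6", 31043931, "G", "C", 0.59, 0.001, 0.014, 0.975),
    ("rs1227734", "19", 18501034, "T", "C", 0.14, 0.066, 0.020, 6.8e-4),
    ("rs60164552", "19", 18488285, "G", "C", 0.92, -0.026, 0.027, 0.337),
    ("rs112253475", "19", 18841757, "A", "G", 0.98, -0.015, 0.062, 0.806),
]

_FINNGEN_OUTCOME_ROWS = [
    ("rs2517481", "6", 31043931, "G", "C", 0.59, 0.001, 0.014, 0.971),
    ("rs1227734", "19", 18501034, "T", "C", 0.14, 0.025, 0.023, 0.281),
    ("rs60164552", "19", 18488285, "G", "C", 0.92, 0.032, 0.024, 0.175),
    ("rs118170439", "19", 18841757, "A", "G", 0.98, 0.006, 0.038, 0.871),
]

#: rsID → rsID linkage-proxy substitutions needed for the FinnGen outcome.
FINNGEN_PROXIES: dict[str, str] = {"rs112253475": "rs118170439"}

_OUTCOME_TABLES = {
    "ukb": (_UKB_OUTCOME_ROWS, "gallstones_ukb", 361194),
    "finngen": (_FINNGEN_OUTCOME_ROWS, "gallstones_finngen", 214167),
}


def _rows_to_dataset(rows, label: str, n: int | None) -> GwasDataset:
    recs = [
        VariantAssociation(
            snp_id=r[0], chrom=r[1], pos=r[2], effect_allele=r[3], other_allele=r[4],
            eaf=r[5], beta=r[6], se=r[7], pvalue=r[8],
        )
        for r in rows
    ]
    return GwasDataset.from_records(label, recs, n)


def reference_instruments(dataset: str) -> tuple[GwasDataset, GwasDataset]:
    """The embedded published instrument table.

    Parameters
    ----------
    dataset
        ``"ukb"`` or ``"finngen"`` — which gallstone outcome GWAS to pair
        with the GDF-15 exposure associations.

    Returns the exposure dataset (four SNPs) and the requested outcome
    dataset.  For FinnGen the fourth instrument is keyed by its proxy rsID;
    pass :data:`FINNGEN_PROXIES` to :func:`harmonize` (or use
    :func:`harmonized_reference`) to resolve it.
    """
    key = dataset.lower()
    if key not in _OUTCOME_TABLES:
        raise KeyError(f"unknown dataset {dataset!r}; expected 'ukb' or 'finngen'")
    rows, label, n = _OUTCOME_TABLES[key]
    exposure = _rows_to_dataset(_EXPOSURE_ROWS, "gdf15", 21758)
    return exposure, _rows_to_dataset(rows, label, n)


def harmonized_reference(dataset: str, palindromic_maf_window: float = 0.08) -> list[HarmonizedInstrument]:
    """Harmonized instruments for one of the embedded outcome datasets."""
    exposure, outcome = reference_instruments(dataset)
    proxies = FINNGEN_PROXIES if dataset.lower() == "finngen" else None
    return harmonize(exposure, outcome, proxy_map=proxies, palindromic_maf_window=palindromic_maf_window)
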