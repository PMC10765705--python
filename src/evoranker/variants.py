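"""Variant filtering: from an annotated variant table to candidate genes.

The front end of the prioritization pipeline.  Annotated exome variants
are filtered on three axes — variant class, population frequency, and
predicted deleteriousness — under a stated inheritance mode, and the
genes whose variants survive become the *patient candidate genes*:

- class: intronic, UTR and ncRNA variants are excluded; nonsense,
  frameshift, nonsynonymous and splice-site variants are kept, plus
  synonymous variants with a splicing-effect score >= 0.5;
- frequency: recessive mode requires every present frequency source
  (gnomAD, popmax, in-house) <= 0.02, dominant mode < 0.001; a variant
  with no frequency data is treated as novel and passes;
- deleteriousness: truncating classes pass unconditionally; splice-site
  and synonymous variants need dbscSNV RF/ADA or SpliceAI >= 0.5;
  nonsynonymous variants need Polyphen2-HDIV >= 0.5 or REVEL >= 0.5 or
  SIFT <= 0.5, with all-missing predictors passing (a variant is only
  excluded when affirmatively predicted benign).

Gene qualification: recessive mode needs a passing hom/hemi variant or
>= 2 distinct passing het variants (unphased compound-het proxy);
dominant mode needs any passing variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "CandidateGeneSet",
    "EFFECT_CLASSES",
    "passes_class_filter",
    "passes_frequency",
    "passes_deleteriousness",
    "filter_variants",
    "read_variant_table",
    "read_variants_vcf",
]

EFFECT_CLASSES = (
    "nonsense",
    "frameshift",
    "nonsynonymous",
    "splice_site",
    "synonymous",
    "intronic",
    "UTR",
    "ncRNA",
    "other",
)

TRUNCATING = ("nonsense", "frameshift")
SPLICING_CLASSES = ("splice_site", "synonymous")

#: ANNOVAR effect vocabulary -> canonical effect classes.
ANNOVAR_EFFECTS = {
    "stopgain": "nonsense",
    "stoploss": "nonsense",
    "frameshift insertion": "frameshift",
    "frameshift deletion": "frameshift",
    "frameshift substitution": "frameshift",
    "nonsynonymous snv": "nonsynonymous",
    "splicing": "splice_site",
    "synonymous snv": "synonymous",
    "intronic": "intronic",
    "utr3": "UTR",
    "utr5": "UTR",
    "ncrna": "ncRNA",
    "ncrna_exonic": "ncRNA",
    "ncrna_intronic": "ncRNA",
}

#: Canonical field -> default input column name (ANNOVAR-style dialect).
DEFAULT_COLUMN_MAP = {
    "gene": "Gene",
    "effect_class": "Effect",
    "zygosity": "Zygosity",
    "freq_gnomad": "gnomAD_AF",
    "freq_popmax": "AF_popmax",
    "freq_inhouse": "InHouse_AF",
    "dbscsnv_rf": "dbscSNV_RF_SCORE",
    "dbscsnv_ada": "dbscSNV_ADA_SCORE",
    "spliceai": "SpliceAI",
    "polyphen2_hdiv": "Polyphen2_HDIV_score",
    "revel": "REVEL",
    "sift": "SIFT_score",
    "variant_id": "VariantID",
}


class VariantError(ValueError):
    pass


@dataclass
class VariantRecord:
    """One annotated variant row on the canonical field set.

    All score/frequency fields are in [0, 1] or ``None`` for missing.
    ``variant_id`` distinguishes het variants for the compound-het rule.
    """

    gene: str
    effect_class: str
    zygosity: str  # hom | het | hemi
    freq_gnomad: float | None = None
    freq_popmax: float | None = None
    freq_inhouse: float | None = None
    dbscsnv_rf: float | None = None
    dbscsnv_ada: float | None = None
    spliceai: float | None = None
    polyphen2_hdiv: float | None = None
    revel: float | None = None
    sift: float | None = None
    variant_id: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise VariantError("variant with empty gene id")
        if self.effect_class not in EFFECT_CLASSES:
            raise VariantError(f"unknown effect class: {self.effect_class!r}")
        if self.zygosity not in ("hom", "het", "hemi"):
            raise VariantError(f"unknown zygosity: {self.zygosity!r}")
        for name in (
            "freq_gnomad", "freq_popmax", "freq_inhouse", "dbscsnv_rf",
            "dbscsnv_ada", "spliceai", "polyphen2_hdiv", "revel", "sift",
        ):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise VariantError(f"{name} out of [0, 1]: {v}")

    @property
    def splicing_scores(self) -> list[float]:
        return [
            s for s in (self.dbscsnv_rf, self.dbscsnv_ada, self.spliceai) if s is not None
        ]


@dataclass
class CandidateGeneSet:
    mode: str  # recessive | dominant
    genes: set[str]
    supporting_variants: dict[str, list[VariantRecord]] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def passes_class_filter(v: VariantRecord) -> bool:
    """Keep prioritized classes; synonymous only with a splicing signal."""
    if v.effect_class in ("nonsense", "frameshift", "nonsynonymous", "splice_site"):
        return True
    if v.effect_class == "synonymous":
        return any(s >= 0.5 for s in v.splicing_scores)
    return False


def passes_frequency(v: VariantRecord, mode: str) -> bool:
    """All present frequency sources under the mode's threshold; a variant
    with no frequency data is novel and passes."""
    freqs = [f for f in (v.freq_gnomad, v.freq_popmax, v.freq_inhouse) if f is not None]
    if mode == "recessive":
        return all(f <= 0.02 for f in freqs)
    if mode == "dominant":
        return all(f < 0.001 for f in freqs)
    raise VariantError(f"unknown inheritance mode: {mode!r}")


def passes_deleteriousness(v: VariantRecord, sift_cutoff: float = 0.5) -> bool:
    """Truncating variants pass; others need a supporting predictor.

    The SIFT cutoff defaults to 0.5 (overridable); nonsynonymous
    variants with no predictor score at all pass, since they cannot be
    affirmatively predicted benign.
    """
    if v.effect_class in TRUNCATING:
        return True
    if v.effect_class in SPLICING_CLASSES:
        return any(s >= 0.5 for s in v.splicing_scores)
    if v.effect_class == "nonsynonymous":
        preds = (v.polyphen2_hdiv, v.revel, v.sift)
        if all(p is None for p in preds):
            return True
        return (
            (v.polyphen2_hdiv is not None and v.polyphen2_hdiv >= 0.5)
            or (v.revel is not None and v.revel >= 0.5)
            or (v.sift is not None and v.sift <= sift_cutoff)
        )
    return False


def filter_variants(
    records: Iterable[VariantRecord],
    mode: str,
    sift_cutoff: float = 0.5,
) -> CandidateGeneSet:
    """Apply all three filters and the inheritance-mode gene rule."""
    records = list(records)
    if not records:
        warnings.warn("empty variant table; no candidate genes")
    report = {"input": len(records), "class": 0, "frequency": 0, "deleteriousness": 0}
    passing: dict[str, list[VariantRecord]] = {}
    for v in records:
        if not passes_class_filter(v):
            continue
        report["class"] += 1
        if not passes_frequency(v, mode):
            continue
        report["frequency"] += 1
        if not passes_deleteriousness(v, sift_cutoff=sift_cutoff):
            continue
        report["deleteriousness"] += 1
        passing.setdefault(v.gene, []).append(v)

    genes: set[str] = set()
    supporting: dict[str, list[VariantRecord]] = {}
    for gene, vs in passing.items():
        if mode == "dominant":
            qualifies = True
        else:
            has_biallelic = any(v.zygosity in ("hom", "hemi") for v in vs)
            het_ids = {v.variant_id or id(v) for v in vs if v.zygosity == "het"}
            qualifies = has_biallelic or len(het_ids) >= 2
        if qualifies:
            genes.add(gene)
            supporting[gene] = vs
    report["genes"] = len(genes)
    return CandidateGeneSet(mode=mode, genes=genes, supporting_variants=supporting, report=report)


def _norm_effect(value: str) -> str:
    key = str(value).strip().lower()
    if key in ANNOVAR_EFFECTS:
        return ANNOVAR_EFFECTS[key]
    if value in EFFECT_CLASSES:
        return value
    for cls in EFFECT_CLASSES:
        if key == cls.lower():
            return cls
    return "other"


def _norm_zygosity(value: str) -> str:
    key = str(value).strip().lower()
    return {"hom": "hom", "homozygous": "hom", "het": "het", "heterozygous": "het",
            "hemi": "hemi", "hemizygous": "hemi"}.get(key, key)


def _get_float(row: Mapping, col: str | None) -> float | None:
    if col is None or col not in row:
        return None
    v = row[col]
    if v is None or (isinstance(v, str) and v.strip() in ("", ".", "NA")):
        return None
    v = float(v)
    return None if pd.isna(v) else v


def records_from_frame(
    df: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> list[VariantRecord]:
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    for required in ("gene", "effect_class", "zygosity"):
        if cmap[required] not in df.columns:
            raise VariantError(f"missing required column {cmap[required]!r}")
    out = []
    for i, row in enumerate(df.to_dict("records")):
        out.append(
            VariantRecord(
                gene=str(row[cmap["gene"]]),
                effect_class=_norm_effect(row[cmap["effect_class"]]),
                zygosity=_norm_zygosity(row[cmap["zygosity"]]),
                freq_gnomad=_get_float(row, cmap.get("freq_gnomad")),
                freq_popmax=_get_float(row, cmap.get("freq_popmax")),
                freq_inhouse=_get_float(row, cmap.get("freq_inhouse")),
                dbscsnv_rf=_get_float(row, cmap.get("dbscsnv_rf")),
                dbscsnv_ada=_get_float(row, cmap.get("dbscsnv_ada")),
                spliceai=_get_float(row, cmap.get("spliceai")),
                polyphen2_hdiv=_get_float(row, cmap.get("polyphen2_hdiv")),
                revel=_get_float(row, cmap.get("revel")),
                sift=_get_float(row, cmap.get("sift")),
                variant_id=str(row.get(cmap.get("variant_id"), "") or f"row{i}"),
            )
        )
    return out


def read_variant_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[VariantRecord]:
    """Read an annotated variant TSV using the (configurable) column map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return records_from_frame(df, column_map)


def read_variants_vcf(
    path: str | Path, info_map: Mapping[str, str] | None = None
) -> list[VariantRecord]:
    """Read variants from a VCF whose INFO fields carry the annotations.

    INFO keys default to the canonical column names of the TSV dialect
    (``Gene``, ``Effect``, ...); zygosity comes from the first sample's
    genotype.  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    cmap = dict(DEFAULT_COLUMN_MAP)
    if info_map:
        cmap.update(info_map)
    out = []
    for i, rec in enumerate(VCF(str(path))):
        info = dict(rec.INFO)
        gene = info.get(cmap["gene"])
        if gene is None:
            raise VariantError(f"VCF record {rec.CHROM}:{rec.POS} lacks a gene INFO field")
        if cmap["zygosity"] in info:
            zyg = _norm_zygosity(info[cmap["zygosity"]])
        else:
            gts = rec.gt_types  # 0=hom-ref 1=het 2=unknown 3=hom-alt
            zyg = "hom" if len(gts) and gts[0] == 3 else "het"
        out.append(
            VariantRecord(
                gene=str(gene),
                effect_class=_norm_effect(info.get(cmap["effect_class"], "other")),
                zygosity=zyg,
                freq_gnomad=_get_float(info, cmap.get("freq_gnomad")),
                freq_popmax=_get_float(info, cmap.get("freq_popmax")),
                freq_inhouse=_get_float(info, cmap.get("freq_inhouse")),
                dbscsnv_rf=_get_float(info, cmap.get("dbscsnv_rf")),
                dbscsnv_ada=_get_float(info, cmap.get("dbscsnv_ada")),
                spliceai=_get_float(info, cmap.get("spliceai")),
                polyphen2_hdiv=_get_float(info, cmap.get("polyphen2_hdiv")),
                revel=_get_float(info, cmap.get("revel")),
                sift=_get_float(info, cmap.get("sift")),
                variant_id=f"{rec.CHROM}:{rec.POS}:{rec.REF}>{','.join(rec.ALT)}",
            )
        )
    return out
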