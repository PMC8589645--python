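"""CNV class assignment and the per-sample carrier matrix.

A QC-passing call is assigned to zero or more classes:

* ``decipher`` — at least 50% of the call overlaps a known CNV-syndrome
  region (dosage ignored by default; strict mode requires the region's
  del/dup annotation to match the call).
* ``id_gene_del`` — a deletion touching >= 50% of the exons of a gene
  curated as monogenically causal for intellectual disability.
* ``high_pli_del`` — a deletion touching >= 50% of the exons of a gene
  with pLI >= 0.95.
* ``large_del`` / ``large_dup`` — a deletion/duplication strictly greater
  than 1 Mb.
* ``ea_assoc`` / ``income_assoc`` / ``medical_assoc`` — >= 50% of the call
  lies within a phenotype-associated locus of matching dosage type.

``high_risk`` is the OR of the first five; one call may satisfy several
classes, and one carrier may have several high-risk calls but is counted
once in any per-class carrier count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import (
    CnvCall,
    GeneModel,
    RegionSet,
    covered_fraction,
    exon_hit_fraction,
)

__all__ = [
    "CnvClassFlags",
    "CLASS_COLUMNS",
    "classify_call",
    "classify_calls",
    "build_carrier_matrix",
    "carrier_summary",
]

CLASS_COLUMNS = [
    "decipher", "id_gene_del", "high_pli_del", "large_del", "large_dup",
    "ea_assoc", "income_assoc", "medical_assoc", "high_risk",
]

HIGH_RISK_CLASSES = CLASS_COLUMNS[:5]

LARGE_BP = 1_000_000  # "greater than 1 Mb" -> strict >
OVERLAP_FRACTION = 0.5  # ">= 50%" rules, inclusive
EXON_FRACTION = 0.5
PLI_THRESHOLD = 0.95


@dataclass(frozen=True)
class CnvClassFlags:
    decipher: bool = False
    id_gene_del: bool = False
    high_pli_del: bool = False
    large_del: bool = False
    large_dup: bool = False
    ea_assoc: bool = False
    income_assoc: bool = False
    medical_assoc: bool = False

    @property
    def high_risk(self) -> bool:
        return (self.decipher or self.id_gene_del or self.high_pli_del
                or self.large_del or self.large_dup)

    def as_dict(self) -> dict[str, bool]:
        d = asdict(self)
        d["high_risk"] = self.high_risk
        return d


def _dosage_subset(rs: RegionSet, call: CnvCall) -> RegionSet:
    want = "del" if call.is_deletion else "dup"
    return rs.subset(lambda a: a.get("dosage", want) == want)


def classify_call(
    call: CnvCall,
    decipher: RegionSet | None = None,
    genes: Sequence[GeneModel] = (),
    assoc_loci: Mapping[str, RegionSet] | None = None,
    strict_decipher_dosage: bool = False,
) -> CnvClassFlags:
    """Evaluate every class rule against one QC-passing call.

    ``assoc_loci`` maps {"ea", "income", "medical"} to dosage-annotated
    region sets; associated-locus matching always requires the call's
    dosage type to match the locus annotation. Genes with missing pLI are
    treated as not loss-of-function intolerant.
    """
    flags = {}
    iv = call.interval

    if decipher is not None and len(decipher):
        rs = _dosage_subset(decipher, call) if strict_decipher_dosage else decipher
        flags["decipher"] = covered_fraction(iv, rs) >= OVERLAP_FRACTION

    if call.is_deletion and genes:
        id_hit = pli_hit = False
        for g in genes:
            if g.interval.chrom != iv.chrom:
                continue
            if not (g.is_id_gene or (g.pli is not None and g.pli >= PLI_THRESHOLD)):
                continue
            if exon_hit_fraction(call, g) >= EXON_FRACTION:
                if g.is_id_gene:
                    id_hit = True
                if g.pli is not None and g.pli >= PLI_THRESHOLD:
                    pli_hit = True
        flags["id_gene_del"] = id_hit
        flags["high_pli_del"] = pli_hit

    flags["large_del"] = call.is_deletion and call.length > LARGE_BP
    flags["large_dup"] = call.is_duplication and call.length > LARGE_BP

    if assoc_loci:
        for key, col in (("ea", "ea_assoc"), ("income", "income_assoc"),
                         ("medical", "medical_assoc")):
            rs = assoc_loci.get(key)
            if rs is None or not len(rs):
                continue
            flags[col] = (
                covered_fraction(iv, _dosage_subset(rs, call))
                >= OVERLAP_FRACTION
            )

    return CnvClassFlags(**flags)


def classify_calls(
    calls: Sequence[CnvCall],
    decipher: RegionSet | None = None,
    genes: Sequence[GeneModel] = (),
    assoc_loci: Mapping[str, RegionSet] | None = None,
    strict_decipher_dosage: bool = False,
) -> pd.DataFrame:
    """Per-call flag table: one row per call with identity columns plus a
    boolean column per class."""
    rows = []
    for c in calls:
        f = classify_call(c, decipher, genes, assoc_loci,
                          strict_decipher_dosage)
        row = {
            "sample_id": c.sample_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "cn_state": c.cn_state,
            "length": c.length,
        }
        row.update(f.as_dict())
        rows.append(row)
    cols = ["sample_id", "chrom", "start", "end", "cn_state", "length"] + CLASS_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def build_carrier_matrix(
    samples: Iterable[str], classified_calls: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample carrier matrix: boolean OR over each sample's call flags.

    ``samples`` is the full roster; samples with zero calls appear with
    all-false flags. A call referencing an unknown sample is an error.
    """
    roster = pd.Index(list(samples), name="sample_id")
    if roster.has_duplicates:
        raise ValueError("duplicate sample ids in roster")
    matrix = pd.DataFrame(False, index=roster, columns=CLASS_COLUMNS)
    if len(classified_calls):
        unknown = set(classified_calls["sample_id"]) - set(roster)
        if unknown:
            raise ValueError(
                f"calls reference samples not in roster: {sorted(unknown)[:5]}"
            )
        per_sample = classified_calls.groupby("sample_id")[CLASS_COLUMNS].any()
        matrix.loc[per_sample.index] = per_sample
    return matrix


def carrier_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Carrier counts and frequencies per class, in the style of a cohort
    frequency table: n carriers and percent of the roster."""
    n_total = len(matrix)
    counts = matrix[CLASS_COLUMNS].sum()
    out = pd.DataFrame({
        "n_carriers": counts.astype(int),
        "frequency": counts / n_total if n_total else 0.0,
    })
    out["percent"] = (100 * out["frequency"]).round(2)
    out.index.name = "cnv_class"
    return out
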