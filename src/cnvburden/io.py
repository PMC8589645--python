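"""Readers and writers for the text dialects the pipeline consumes.

Supported call dialects:

* ``penncnv_rawcnv`` — whitespace-separated PennCNV .rawcnv lines, e.g.::

      chr1:100001-200000  numsnp=20  length=100,000  state2,cn=1  sample1  conf=30.1

  Coordinates are 1-based inclusive and converted to canonical 0-based
  half-open on read (length preserved: ``end1 - start1 + 1``).

* ``bed_tsv`` — BED-like TSV, 0-based half-open:
  ``chrom  start  end  sample_id  cn_state  n_probes``.

Region sets are BED3+ (optional columns: name, dosage); gene models a TSV
with comma-separated exon coordinate lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .intervals import CnvCall, GeneModel, GenomicInterval, RegionSet

__all__ = [
    "ParseIssue",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_region_bed",
    "write_region_bed",
    "read_gene_models",
    "write_gene_models",
]

CALL_DIALECTS = ("penncnv_rawcnv", "bed_tsv")

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


@dataclass(frozen=True)
class ParseIssue:
    """A rejected input line with its 1-based line number and reason."""

    line_no: int
    reason: str
    line: str


def _int(tok: str) -> int:
    return int(tok.replace(",", ""))


def _parse_penncnv_line(line: str) -> CnvCall:
    toks = line.split()
    if not toks:
        raise ValueError("empty line")
    m = _REGION_RE.match(toks[0])
    if m is None:
        raise ValueError(f"unparseable region token {toks[0]!r}")
    start1, end1 = _int(m["start"]), _int(m["end"])
    if end1 < start1:
        raise ValueError(f"end before start in {toks[0]!r}")
    cn = n_probes = None
    sample = None
    for tok in toks[1:]:
        if "cn=" in tok:  # may appear as "state2,cn=1"
            cn = _int(tok.split("cn=")[1])
        elif tok.startswith("numsnp="):
            n_probes = _int(tok.split("=", 1)[1])
        elif "=" not in tok and sample is None:
            sample = tok
    if cn is None:
        raise ValueError("missing cn= field")
    if n_probes is None:
        raise ValueError("missing numsnp= field")
    if sample is None:
        raise ValueError("missing sample field")
    # 1-based inclusive -> 0-based half-open
    return CnvCall(
        sample_id=sample,
        interval=GenomicInterval(m["chrom"], start1 - 1, end1),
        cn_state=cn,
        n_probes=n_probes,
        source="penncnv",
    )


def _parse_bed_line(line: str) -> CnvCall:
    toks = line.split("\t") if "\t" in line else line.split()
    if len(toks) < 6:
        raise ValueError("expected 6 columns: chrom start end sample cn n_probes")
    chrom, start, end, sample, cn, n_probes = toks[:6]
    return CnvCall(
        sample_id=sample,
        interval=GenomicInterval(chrom, _int(start), _int(end)),
        cn_state=_int(cn),
        n_probes=_int(n_probes),
        source="bed",
    )


def read_cnv_calls(
    path: str | Path, dialect: str = "penncnv_rawcnv"
) -> tuple[list[CnvCall], list[ParseIssue]]:
    """Read CNV calls, returning (calls, issues).

    Malformed lines (including cn=2 "calls") never abort the read; they are
    reported as :class:`ParseIssue` records with their line numbers.
    """
    if dialect not in CALL_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {CALL_DIALECTS}")
    parse = _parse_penncnv_line if dialect == "penncnv_rawcnv" else _parse_bed_line
    calls: list[CnvCall] = []
    issues: list[ParseIssue] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                calls.append(parse(line))
            except (ValueError, IndexError) as exc:
                issues.append(ParseIssue(i, str(exc), line))
    return calls, issues


def write_cnv_calls(
    calls: Iterable[CnvCall], path: str | Path, dialect: str = "penncnv_rawcnv"
) -> None:
    """Write calls in the given dialect (inverse of :func:`read_cnv_calls`)."""
    if dialect not in CALL_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            if dialect == "penncnv_rawcnv":
                state = f"state{c.cn_state},cn={c.cn_state}"
                fh.write(
                    f"{iv.chrom}:{iv.start + 1}-{iv.end}\tnumsnp={c.n_probes}\t"
                    f"length={iv.length}\t{state}\t{c.sample_id}\n"
                )
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.sample_id}\t"
                    f"{c.cn_state}\t{c.n_probes}\n"
                )


def read_region_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED3+ file into a RegionSet.

    Column 4 (if present) is the region name; column 5 (if present and one
    of del/dup) the dosage type.
    """
    regions: list[tuple[GenomicInterval, dict]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split("\t") if "\t" in line else line.split()
            iv = GenomicInterval(toks[0], _int(toks[1]), _int(toks[2]))
            attrs: dict = {}
            if len(toks) > 3 and toks[3] != ".":
                attrs["name"] = toks[3]
            if len(toks) > 4 and toks[4] in ("del", "dup"):
                attrs["dosage"] = toks[4]
            regions.append((iv, attrs))
    return RegionSet(name or Path(path).stem, regions)


def write_region_bed(rs: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, attrs in rs:
            name = attrs.get("name", ".")
            dosage = attrs.get("dosage", "")
            cols = [iv.chrom, str(iv.start), str(iv.end), name]
            if dosage:
                cols.append(dosage)
            fh.write("\t".join(cols) + "\n")


_GENE_COLS = [
    "gene_id", "chrom", "start", "end", "exon_starts", "exon_ends",
    "pli", "is_id_gene",
]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from TSV (gene, chrom, start, end, exon coordinate
    lists, pLI, ID-gene flag). Missing pLI is an empty field or 'NA'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"gene model file missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        chrom = row.chrom
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise ValueError(f"exon start/end count mismatch for {row.gene_id}")
        exons = tuple(
            GenomicInterval(chrom, s, e) for s, e in zip(starts, ends)
        )
        pli_raw = row.pli
        pli = None if pli_raw in (None, "", "NA", "nan") else float(pli_raw)
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                interval=GenomicInterval(chrom, int(row.start), int(row.end)),
                exons=exons,
                pli=pli,
                is_id_gene=str(row.is_id_gene).lower() in ("1", "true", "yes"),
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "exon_starts": ",".join(str(e.start) for e in g.exons),
            "exon_ends": ",".join(str(e.end) for e in g.exons),
            "pli": "" if g.pli is None else g.pli,
            "is_id_gene": int(g.is_id_gene),
        })
    pd.DataFrame(rows, columns=_GENE_COLS).to_csv(path, sep="\t", index=False)
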