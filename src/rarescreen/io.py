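"""Readers and writers for the formats the pipeline touches.

VCF v4.2 (GT-only) for cohort genotypes, a gnomAD-style TSV sidecar for
variant annotation, a one-symbol-per-line gene list, a YAML/JSON evidence
checklist, an ancestry-informative-marker (AIM) panel TSV, and a
pre-tabulated allele-counts TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .core import (
    MISSING,
    POPULATIONS,
    AlleleCount,
    CohortGenotypes,
    PopulationFrequencies,
    VariantKey,
    VariantRecord,
)

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "rsid", "gene", "transcript",
    "consequence", "lof_confidence", "af_global",
    "af_afr", "af_amr", "af_eas", "af_sas", "af_eur", "ancestry",
]

_POP_COLUMNS = {"AFR": "af_afr", "AMR": "af_amr", "EAS": "af_eas",
                "SAS": "af_sas", "EUR": "af_eur"}

#: Manual evidence flags carried by the checklist config.
MANUAL_CRITERIA = (
    "sanger_validated",
    "selective_pressure",
    "heterozygous_impact_plausible",
    "plausible_pathophysiology",
)


class VcfParseError(ValueError):
    pass


class DuplicateRecordError(ValueError):
    pass


class AnnotationSchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# annotation table


class AnnotationTable:
    """Per-variant annotation keyed by (chrom, pos, ref, alt).

    Each entry pairs a :class:`VariantRecord` with its population
    frequencies and a curated ancestry label. The curated label may disagree
    with the argmax of per-population frequencies; downstream code prefers
    the computed call and logs disagreements.
    """

    def __init__(self, rows: Mapping[VariantKey, tuple[VariantRecord, PopulationFrequencies, Optional[str]]]):
        self._rows = dict(rows)

    def __len__(self) -> int:
        return len(self._rows)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._rows

    def __iter__(self):
        return iter(self._rows)

    def keys(self):
        return self._rows.keys()

    def record(self, key: VariantKey) -> VariantRecord:
        return self._rows[key][0]

    def frequencies(self, key: VariantKey) -> PopulationFrequencies:
        return self._rows[key][1]

    def ancestry_label(self, key: VariantKey) -> Optional[str]:
        return self._rows[key][2]

    @classmethod
    def from_records(cls, entries) -> "AnnotationTable":
        """Build from (record, frequencies, ancestry_label) triples."""
        rows = {}
        for record, freqs, label in entries:
            if record.key in rows:
                raise DuplicateRecordError(f"duplicate annotation key {record.key}")
            rows[record.key] = (record, freqs, label)
        return cls(rows)

    def to_dataframe(self) -> pd.DataFrame:
        out = []
        for record, freqs, label in self._rows.values():
            row = {
                "chrom": record.chrom, "pos": record.pos, "ref": record.ref,
                "alt": record.alt, "rsid": record.rsid, "gene": record.gene,
                "transcript": record.transcript, "consequence": record.consequence,
                "lof_confidence": record.lof_confidence,
                "af_global": freqs.af_global, "ancestry": label,
            }
            for pop, col in _POP_COLUMNS.items():
                row[col] = freqs.af_by_pop.get(pop)
            out.append(row)
        return pd.DataFrame(out, columns=ANNOTATION_COLUMNS)


def _parse_af(value) -> Optional[float]:
    """Frequency cell -> float in [0,1], None if blank, ValueError if bad."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    af = float(value)
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    return af


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read the gnomAD-style annotation TSV.

    Rows whose frequency fields fail to parse (non-numeric or outside
    [0, 1]) are rejected with a logged reason rather than aborting the load;
    a missing mandatory column is a schema error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationSchemaError(f"annotation file missing columns: {sorted(missing)}")
    entries = []
    for idx, row in df.iterrows():
        try:
            af_global = _parse_af(row["af_global"])
            af_by_pop = {pop: _parse_af(row[col]) for pop, col in _POP_COLUMNS.items()}
            record = VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                rsid=None if pd.isna(row["rsid"]) else str(row["rsid"]),
                gene=None if pd.isna(row["gene"]) else str(row["gene"]),
                transcript=None if pd.isna(row["transcript"]) else str(row["transcript"]),
                consequence=str(row["consequence"]),
                lof_confidence=str(row["lof_confidence"]),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("annotation row %d rejected: %s", idx, exc)
            continue
        label = None if pd.isna(row["ancestry"]) else str(row["ancestry"])
        freqs = PopulationFrequencies(af_global=af_global, af_by_pop=af_by_pop)
        entries.append((record, freqs, label))
    return AnnotationTable.from_records(entries)


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def read_vcf(path: str | Path, cohort_label: str) -> CohortGenotypes:
    """Read a multi-sample VCF into a cohort dosage matrix.

    Multi-allelic sites are split into one record per alt allele with
    per-alt dosage; ``./.`` becomes missing; subject order follows the
    header. Duplicate (chrom, pos, ref, alt) records are an error.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    subjects = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    seen: set[VariantKey] = set()
    for var in vcf:
        genos = var.genotypes  # [[a0, a1, phased], ...]
        for alt_index, alt in enumerate(var.ALT, start=1):
            record = VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alt,
                rsid=var.ID,
            )
            if record.key in seen:
                raise DuplicateRecordError(f"duplicate record {record.key} in {path}")
            seen.add(record.key)
            col = np.empty(len(subjects), dtype=np.int8)
            for i, g in enumerate(genos):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    col[i] = MISSING
                else:
                    col[i] = sum(1 for a in alleles if a == alt_index)
            variants.append(record)
            columns.append(col)
    matrix = (
        np.column_stack(columns) if columns else np.zeros((len(subjects), 0), dtype=np.int8)
    )
    return CohortGenotypes(label=cohort_label, subjects=subjects, variants=variants, genotypes=matrix)


def _gt_string(dosage: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}[int(dosage)]


def write_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Write a GT-only VCF v4.2, records sorted by (chrom, pos, ref, alt).

    ``read_vcf(write_vcf(c))`` is the identity on (subjects, variants,
    dosages), and rewriting a written file is byte-identical.
    """
    order = sorted(range(len(cohort.variants)),
                   key=lambda j: cohort.variants[j].key)
    lines = [_VCF_HEADER]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.subjects) + "\n")
    for j in order:
        rec = cohort.variants[j]
        gts = "\t".join(_gt_string(d) for d in cohort.genotypes[:, j])
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.rsid or '.'}\t{rec.ref}\t{rec.alt}"
            f"\t.\t.\t.\tGT\t{gts}\n"
        )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# gene list, evidence config, AIM panel, counts table


def read_gene_list(path: str | Path) -> set[str]:
    """Gene symbols, one per line; case preserved, matching is caller's job."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        symbol = line.strip()
        if symbol and not symbol.startswith("#"):
            genes.add(symbol)
    return genes


def _parse_flag(value) -> Optional[bool]:
    """Three-state evidence flag: True / False / None ("unknown")."""
    if value is None or value == "unknown" or value == "?":
        return None
    if isinstance(value, bool):
        return value
    raise ValueError(f"evidence flag must be true/false/unknown, got {value!r}")


def read_evidence_config(path: str | Path) -> dict[VariantKey, dict[str, Optional[bool]]]:
    """Read the manual evidence checklist (YAML or JSON).

    Layout: a ``variants`` list of entries with chrom/pos/ref/alt plus the
    four manual criteria. "unknown" is a distinct third state, never coerced
    to false.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    out: dict[VariantKey, dict[str, Optional[bool]]] = {}
    for entry in data.get("variants", []):
        key = (str(entry["chrom"]), int(entry["pos"]), str(entry["ref"]), str(entry["alt"]))
        out[key] = {c: _parse_flag(entry.get(c, None)) for c in MANUAL_CRITERIA}
    return out


def read_aim_panel(path: str | Path) -> pd.DataFrame:
    """AIM panel TSV: marker, chrom, pos, counted_allele, f_afr, f_eur."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"marker", "f_afr", "f_eur"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationSchemaError(f"AIM panel missing columns: {sorted(missing)}")
    for col in ("f_afr", "f_eur"):
        bad = ~df[col].between(0.0, 1.0)
        if bad.any():
            raise ValueError(f"AIM panel column {col} has frequencies outside [0, 1]")
    return df


def read_counts_table(path: str | Path) -> list[dict]:
    """Pre-tabulated counts TSV for direct association.

    Columns: key (chrom:pos:ref:alt or an rsid), case_hom, case_het,
    case_total, control_hom, control_het, control_total.
    """
    df = pd.read_csv(path, sep="\t")
    rows = []
    for _, r in df.iterrows():
        rows.append({
            "key": str(r["key"]),
            "case": AlleleCount(int(r["case_hom"]), int(r["case_het"]), int(r["case_total"])),
            "control": AlleleCount(int(r["control_hom"]), int(r["control_het"]), int(r["control_total"])),
        })
    return rows


__all__ = [
    "AnnotationTable",
    "ANNOTATION_COLUMNS",
    "MANUAL_CRITERIA",
    "read_vcf",
    "write_vcf",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "read_evidence_config",
    "read_aim_panel",
    "read_counts_table",
    "VcfParseError",
    "DuplicateRecordError",
    "AnnotationSchemaError",
]
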