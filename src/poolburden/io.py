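"""File formats: pooled-call VCF, reference-panel TSV, annotation TSV.

The pooled call set is VCF 4.2 with one sample column per pool.  Per-sample
FORMAT fields::

    AC_POOL  (Number=A) called alternate chromosomes out of the pool ploidy
    DP       (Number=1) read depth
    GQ       (Number=1) genotype quality
    ADF/ADR  (Number=A) alternate read depth on the forward / reverse strand

The pool ploidy (2 x pool size) is carried in INFO/PLOIDY.  Case pools are
named ``CASE...`` and control pools ``CTRL...``; the reader recovers the
case/control flag from that prefix.  All writers emit a deterministic order
(chrom, pos, alt; samples cases-then-controls as given).
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence

import pandas as pd
import pysam

from .exceptions import ParseError, ValidationError
from .variants import (
    FUNCTIONAL_CLASSES,
    PoolObservation,
    ReferencePanel,
    VariantKey,
    VariantRecord,
    normalize_variant,
)

CASE_POOL_PREFIX = "CASE"
CONTROL_POOL_PREFIX = "CTRL"

PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "panel", "AC", "AN"]
ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "functional_class",
    "cadd_phred",
    "dbsnp_id",
]

_MANDATORY_FORMAT = ("AC_POOL", "DP", "GQ", "ADF", "ADR")


def _chrom_sort_key(chrom: str) -> tuple:
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def _record_sort_key(rec: VariantRecord) -> tuple:
    return (_chrom_sort_key(rec.key.chrom), rec.key.pos, rec.key.ref, rec.key.alt)


def write_pooled_vcf(records: Sequence[VariantRecord], path: str | os.PathLike) -> None:
    """Write a pooled call set as biallelic-split VCF 4.2 (see module docs)."""
    records = sorted(records, key=_record_sort_key)
    sample_names: list[str] = []
    for rec in records:
        for obs in rec.pools:
            if obs.pool_id not in sample_names:
                sample_names.append(obs.pool_id)

    header = pysam.VariantHeader()
    header.add_line("##source=poolburden")
    chroms = sorted({r.key.chrom for r in records}, key=_chrom_sort_key)
    for chrom in chroms:
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line(
        '##INFO=<ID=PLOIDY,Number=1,Type=Integer,Description="Alternate chromosomes per pool (2 x pool size)">'
    )
    header.add_line(
        '##FORMAT=<ID=AC_POOL,Number=A,Type=Integer,Description="Called alternate chromosomes in the pool">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
    )
    # ADF/ADR are reserved Number=R fields (one value per allele, ref first);
    # the ref-strand slot is written as missing since reads are only
    # strand-split for the alternate allele.
    header.add_line(
        '##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Per-allele reads, forward strand">'
    )
    header.add_line(
        '##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Per-allele reads, reverse strand">'
    )
    for name in sample_names:
        header.add_sample(name)

    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for rec in records:
            out = vcf.new_record(
                contig=rec.key.chrom,
                start=rec.key.pos - 1,
                alleles=(rec.key.ref, rec.key.alt),
            )
            if rec.pools:
                out.info["PLOIDY"] = rec.pools[0].ploidy
            by_id = {o.pool_id: o for o in rec.pools}
            for name in sample_names:
                obs = by_id.get(name)
                if obs is None:
                    continue
                sample = out.samples[name]
                sample["AC_POOL"] = (obs.alt_count,)
                sample["DP"] = obs.depth
                sample["GQ"] = obs.gq
                sample["ADF"] = (None, obs.fwd_alt)
                sample["ADR"] = (None, obs.rev_alt)
            vcf.write(out)


def read_pooled_vcf(path: str | os.PathLike) -> list[VariantRecord]:
    """Read a pooled call set; multi-allelic sites are split into one record
    per alternate allele and keys are normalised.

    Raises :class:`ParseError` naming the field and body line number when a
    mandatory FORMAT field is absent.
    """
    path = os.fspath(path)
    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        declared = set(vcf.header.formats.keys())
        missing = [f for f in _MANDATORY_FORMAT if f not in declared]
        if missing:
            raise ParseError(
                f"{path}: missing mandatory FORMAT field(s): {', '.join(missing)}"
            )
        header_lines = str(vcf.header).count("\n")
        for i, site in enumerate(vcf):
            line_no = header_lines + i + 1
            if site.alts is None:
                continue
            ploidy = int(site.info.get("PLOIDY", 20))
            for alt_index, alt in enumerate(site.alts):
                try:
                    key = normalize_variant(
                        VariantKey(site.chrom, site.pos, site.ref, alt)
                    )
                except Exception as exc:
                    raise ParseError(f"{path} line {line_no}: {exc}") from exc
                pools: list[PoolObservation] = []
                for name, sample in site.samples.items():
                    values = {}
                    for fmt in _MANDATORY_FORMAT:
                        value = sample.get(fmt)
                        if value is None:
                            raise ParseError(
                                f"{path} line {line_no}: sample {name} lacks "
                                f"mandatory FORMAT field {fmt}"
                            )
                        values[fmt] = value
                    pools.append(
                        PoolObservation(
                            pool_id=name,
                            alt_count=int(values["AC_POOL"][alt_index]),
                            depth=int(values["DP"]),
                            gq=int(values["GQ"]),
                            fwd_alt=int(values["ADF"][1 + alt_index]),
                            rev_alt=int(values["ADR"][1 + alt_index]),
                            ploidy=ploidy,
                            is_control_pool=name.startswith(CONTROL_POOL_PREFIX),
                        )
                    )
                records.append(VariantRecord(key=key, pools=pools))
    return records


def write_panels_tsv(
    panels: Iterable[ReferencePanel], path: str | os.PathLike
) -> None:
    """Write one or more panels as a single TSV (chrom, pos, ref, alt, panel, AC, AN)."""
    rows = []
    for panel in panels:
        for key, (ac, an) in panel.freqs.items():
            rows.append(
                {
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                    "panel": panel.name,
                    "AC": ac,
                    "AN": an,
                }
            )
    frame = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    frame = frame.sort_values(["panel", "chrom", "pos", "alt"], kind="stable")
    frame.to_csv(path, sep="\t", index=False)


def read_reference_panel(
    path: str | os.PathLike, name: str, n_individuals: int
) -> ReferencePanel:
    """Load the rows of one panel from a panel TSV; keys are normalised.

    Raises :class:`ValidationError` with the 1-based data row number on
    AC > AN or on a duplicate key within the panel.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing panel column(s): {', '.join(missing)}")
    freqs: dict[VariantKey, tuple[int, int]] = {}
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        if row.panel != name:
            continue
        ac, an = int(row.AC), int(row.AN)
        if ac > an:
            raise ValidationError(f"{path} row {row_no}: AC {ac} > AN {an}")
        key = normalize_variant(
            VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        )
        if key in freqs:
            raise ValidationError(
                f"{path} row {row_no}: duplicate entry for {key} in panel {name}"
            )
        freqs[key] = (ac, an)
    return ReferencePanel(name=name, n_individuals=n_individuals, freqs=freqs)


def write_annotations_tsv(
    annotations: pd.DataFrame, path: str | os.PathLike
) -> None:
    frame = annotations.loc[:, ANNOTATION_COLUMNS].copy()
    frame = frame.sort_values(["chrom", "pos", "alt"], kind="stable")
    frame.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "dbsnp_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation column(s): {', '.join(missing)}")
    bad = set(frame["functional_class"].dropna()) - set(FUNCTIONAL_CLASSES)
    if bad:
        raise ValidationError(
            f"{path}: unknown functional class(es): {', '.join(sorted(bad))}"
        )
    return frame


def merge_annotations(
    records: Sequence[VariantRecord], annotation_path: str | os.PathLike
) -> list[VariantRecord]:
    """Attach gene / functional class / CADD / dbSNP id by normalised key.

    Records without an annotation row are retained with ``gene=None`` (the
    class filter excludes them from gene-level stages).  Two annotation rows
    for one key with different genes raise :class:`ValidationError`.
    """
    frame = read_annotations(annotation_path)
    table: dict[VariantKey, dict] = {}
    for row in frame.itertuples(index=False):
        key = normalize_variant(
            VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        )
        entry = {
            "gene": None if pd.isna(row.gene) else str(row.gene),
            "functional_class": None
            if pd.isna(row.functional_class)
            else str(row.functional_class),
            "cadd_phred": None if pd.isna(row.cadd_phred) else float(row.cadd_phred),
            "dbsnp_id": None
            if (row.dbsnp_id is None or pd.isna(row.dbsnp_id) or row.dbsnp_id == "")
            else str(row.dbsnp_id),
        }
        if key in table:
            if table[key]["gene"] != entry["gene"]:
                raise ValidationError(
                    f"conflicting gene assignments for {key}: "
                    f"{table[key]['gene']} vs {entry['gene']}"
                )
            continue
        table[key] = entry
    out = []
    for rec in records:
        entry = table.get(rec.key)
        if entry is not None:
            rec.gene = entry["gene"]
            rec.functional_class = entry["functional_class"]
            rec.cadd_phred = entry["cadd_phred"]
            rec.dbsnp_id = entry["dbsnp_id"]
        out.append(rec)
    return out


def attach_panel_frequencies(
    records: Sequence[VariantRecord], panels: Iterable[ReferencePanel]
) -> list[VariantRecord]:
    """Fill ``panel_freqs`` on each record from the given panels (absent keys
    are simply not attached; the MAF filter flags them as novel)."""
    panels = list(panels)
    for rec in records:
        for panel in panels:
            entry = panel.freqs.get(rec.key)
            if entry is not None:
                rec.panel_freqs[panel.name] = entry
    return list(records)
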