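"""The QC and study-design filter cascade, with an auditable ledger.

Canonical order (frozen in the pipeline config):

    site_quality -> strand_bias -> recurrence -> control_exclusion
        -> functional_class -> maf_threshold

Boundary semantics: a pool observation is invalidated when depth < 10 OR
GQ < 20 (exclusive thresholds).  Although the source description reads
"RD <10 and GQ <20", the disjunctive reading is the one consistent with
hard-filtering intent — a depth-5/GQ-60 call must not survive — and both
thresholds are configurable.

"Observed in a pool" always means a called alternate count > 0 in a pool
whose observation passed QC: control evidence that itself failed QC does not
exclude a variant.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .exceptions import ConfigurationError
from .variants import EXONIC_CLASSES, ReferencePanel, VariantKey, VariantRecord

CANONICAL_ORDER = (
    "site_quality",
    "strand_bias",
    "recurrence",
    "control_exclusion",
    "functional_class",
    "maf_threshold",
)


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_out: int
    n_removed: int
    removed: list[VariantKey]
    params: dict


@dataclass
class FilterLedger:
    """Ordered record of every cascade stage: counts, removed keys, thresholds."""

    stages: list[FilterStage] = field(default_factory=list)

    def record(
        self,
        name: str,
        n_in: int,
        n_out: int,
        removed: Sequence[VariantKey],
        params: dict | None = None,
    ) -> FilterStage:
        stage = FilterStage(
            name=name,
            n_in=n_in,
            n_out=n_out,
            n_removed=n_in - n_out,
            removed=list(removed),
            params=dict(params or {}),
        )
        self.stages.append(stage)
        self.validate_chain()
        return stage

    def validate_chain(self) -> None:
        """n_out = n_in - n_removed within stages; consecutive stages chain;
        counts never increase along the cascade."""
        prev = None
        for stage in self.stages:
            if stage.n_out != stage.n_in - stage.n_removed:
                raise ConfigurationError(
                    f"ledger stage {stage.name}: n_out {stage.n_out} != "
                    f"n_in {stage.n_in} - n_removed {stage.n_removed}"
                )
            if stage.n_removed != len(stage.removed):
                raise ConfigurationError(
                    f"ledger stage {stage.name}: removed-key list does not match count"
                )
            if prev is not None and stage.n_in != prev.n_out:
                raise ConfigurationError(
                    f"ledger stages do not chain: {prev.name} out {prev.n_out} "
                    f"vs {stage.name} in {stage.n_in}"
                )
            prev = stage

    def removed_at(self, name: str) -> set[VariantKey]:
        keys: set[VariantKey] = set()
        for stage in self.stages:
            if stage.name == name:
                keys.update(stage.removed)
        return keys

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "n_removed": s.n_removed,
                    "params": json.dumps(s.params, sort_keys=True),
                }
                for s in self.stages
            ]
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = [
            {
                "stage": s.name,
                "n_in": s.n_in,
                "n_out": s.n_out,
                "n_removed": s.n_removed,
                "params": s.params,
                "removed": [str(k) for k in s.removed],
            }
            for s in self.stages
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]


def site_quality_filter(
    records: Sequence[VariantRecord],
    min_rd: int = 10,
    min_gq: int = 20,
    ledger: FilterLedger | None = None,
) -> list[VariantRecord]:
    """Invalidate pool observations with depth < min_rd or GQ < min_gq;
    drop variants left without any QC-passing case observation carrying the
    alternate allele."""
    kept, removed = [], []
    for rec in records:
        for obs in rec.pools:
            if obs.depth < min_rd or obs.gq < min_gq:
                obs.qc_pass = False
        if any(o.alt_count > 0 for o in rec.case_pools()):
            kept.append(rec)
        else:
            removed.append(rec.key)
    if ledger is not None:
        ledger.record(
            "site_quality",
            len(records),
            len(kept),
            removed,
            {"min_rd": min_rd, "min_gq": min_gq},
        )
    return kept


def strand_bias_filter(
    records: Sequence[VariantRecord],
    min_alt_reads_per_strand: int = 1,
    ledger: FilterLedger | None = None,
) -> list[VariantRecord]:
    """Remove variants supported on only one strand.

    Alternate reads are summed over QC-passing case pools; a variant is
    removed when either strand carries fewer than
    ``min_alt_reads_per_strand`` reads.  Sites with no alternate reads at all
    are removed too and logged distinctly as no-support."""
    kept, removed = [], []
    n_no_support = 0
    for rec in records:
        fwd, rev = rec.case_strand_counts()
        if fwd + rev == 0:
            removed.append(rec.key)
            n_no_support += 1
        elif fwd < min_alt_reads_per_strand or rev < min_alt_reads_per_strand:
            removed.append(rec.key)
        else:
            kept.append(rec)
    if ledger is not None:
        ledger.record(
            "strand_bias",
            len(records),
            len(kept),
            removed,
            {
                "min_alt_reads_per_strand": min_alt_reads_per_strand,
                "n_no_support": n_no_support,
            },
        )
    return kept


def recurrence_filter(
    records: Sequence[VariantRecord],
    min_pools: int = 2,
    ledger: FilterLedger | None = None,
) -> list[VariantRecord]:
    """Keep variants called (alt count > 0) in at least ``min_pools`` distinct
    QC-passing case pools ("found in more than one pool")."""
    kept, removed = [], []
    for rec in records:
        if rec.n_case_pools_with_alt() >= min_pools:
            kept.append(rec)
        else:
            removed.append(rec.key)
    if ledger is not None:
        ledger.record(
            "recurrence", len(records), len(kept), removed, {"min_pools": min_pools}
        )
    return kept


def control_exclusion_filter(
    records: Sequence[VariantRecord],
    ledger: FilterLedger | None = None,
) -> list[VariantRecord]:
    """Remove variants observed in any QC-passing control pool.

    If no control pools exist anywhere a warning is emitted and records pass
    through unchanged."""
    has_controls = any(rec.control_pools(valid_only=False) for rec in records)
    if not has_controls:
        warnings.warn(
            "no control pools present; control exclusion is a pass-through",
            stacklevel=2,
        )
        if ledger is not None:
            ledger.record(
                "control_exclusion",
                len(records),
                len(records),
                [],
                {"no_control_pools": True},
            )
        return list(records)
    kept, removed = [], []
    for rec in records:
        if any(o.alt_count > 0 for o in rec.control_pools()):
            removed.append(rec.key)
        else:
            kept.append(rec)
    if ledger is not None:
        ledger.record("control_exclusion", len(records), len(kept), removed, {})
    return kept


def functional_class_filter(
    records: Sequence[VariantRecord],
    keep: frozenset[str] | set[str] = EXONIC_CLASSES,
    ledger: FilterLedger | None = None,
) -> list[VariantRecord]:
    """Keep records whose functional class is in ``keep``; unannotated
    records (no gene/class) are excluded from gene-level stages here."""
    keep = frozenset(keep)
    kept, removed = [], []
    for rec in records:
        if rec.functional_class is not None and rec.functional_class in keep:
            kept.append(rec)
        else:
            removed.append(rec.key)
    if ledger is not None:
        ledger.record(
            "functional_class",
            len(records),
            len(kept),
            removed,
            {"keep": sorted(keep)},
        )
    return kept


def maf_threshold_filter(
    records: Sequence[VariantRecord],
    panel: ReferencePanel,
    max_maf: float,
    ledger: FilterLedger | None = None,
) -> list[VariantRecord]:
    """Keep variants whose panel alternate-allele frequency is below
    ``max_maf``.  Variants absent from the panel count as frequency 0: they
    are kept and flagged novel-in-panel on the record."""
    if not 0.0 < max_maf <= 1.0:
        raise ConfigurationError(f"max_maf must lie in (0, 1], got {max_maf}")
    kept, removed = [], []
    for rec in records:
        af = panel.af(rec.key)
        if af is None:
            rec.novel_in.add(panel.name)
            kept.append(rec)
        elif af < max_maf:
            kept.append(rec)
        else:
            removed.append(rec.key)
    if ledger is not None:
        ledger.record(
            "maf_threshold",
            len(records),
            len(kept),
            removed,
            {"panel": panel.name, "max_maf": max_maf},
        )
    return kept
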