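"""Per-variant and per-gene case/control association statistics.

The core computation: cohort allele frequencies, cross-product odds ratios
with Woolf (log-normal) 95% confidence intervals, one-sided Fisher exact
p-values in the case-enrichment direction, per-gene Bonferroni correction by
the gene's own variant count, and the gene-level allele-count burden test
aggregating alternate alleles across a gene into one 2x2 table per reference
panel.

The modelling surface follows the statsmodels convention: build a
:class:`GeneBurdenModel` from cascade-filtered records, call ``fit()``, and
read estimates off the returned :class:`GeneBurdenResults` (``.frame``,
``.summary()``, ``.significant()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .exceptions import ConfigurationError, ValidationError
from .variants import ReferencePanel, VariantRecord

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 allele-count table: cases (a alt, b ref) vs panel (c alt, d ref)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative cell in contingency table {self}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class AssociationResult:
    """OR with 95% CI, one-sided Fisher p, Bonferroni-corrected p, and the
    variant count m the correction used (1 for per-variant results)."""

    unit: object
    panel: str
    or_point: float  # NaN when undefined
    ci_low: float
    ci_high: float
    p: float
    p_corrected: float
    m: int = 1
    note: str | None = None


def cohort_maf(alt_allele_count: int, n_individuals: int) -> float:
    """Cohort alternate-allele frequency AC / (2N)."""
    if n_individuals <= 0:
        raise ConfigurationError("n_individuals must be positive")
    if not 0 <= alt_allele_count <= 2 * n_individuals:
        raise ValidationError(
            f"alt allele count {alt_allele_count} outside [0, {2 * n_individuals}]"
        )
    return alt_allele_count / (2 * n_individuals)


def fisher_one_sided(table: ContingencyTable | tuple[int, int, int, int]) -> float:
    """One-sided Fisher exact p in the case-enrichment direction.

    With margins fixed, the case alternate count follows a hypergeometric
    law; the p-value is the upper-tail probability of observing at least the
    table's ``a``.  Computed through the hypergeometric survival function
    (log-space internals), exact for cell totals well beyond 1e6.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = table.cells
    total = a + b + c + d
    if total == 0:
        return 1.0
    p = float(hypergeom.sf(a - 1, total, a + c, a + b))
    return min(max(p, 0.0), 1.0)


def bonferroni_correct(p: float, m: int) -> float:
    """min(1, m * p) — correction by the gene's own variant count."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if m < 1:
        raise ValidationError(f"variant count m must be >= 1, got {m}")
    return min(1.0, m * p)


def odds_ratio_ci(
    table: ContingencyTable | tuple[int, int, int, int],
    zero_cell_correction: float = 0.5,
) -> tuple[float, float, float]:
    """Cross-product odds ratio with Woolf log-normal 95% CI.

    Any zero cell triggers the Haldane-Anscombe correction (add
    ``zero_cell_correction`` to all four cells) for the OR and CI only.
    Returns (or_point, ci_low, ci_high); NaNs when no alternate allele was
    seen in either group.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = (float(x) for x in table.cells)
    if a == 0 and c == 0:
        return (math.nan, math.nan, math.nan)
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + zero_cell_correction for x in (a, b, c, d))
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_point)
    return (
        or_point,
        math.exp(log_or - Z_95 * se),
        math.exp(log_or + Z_95 * se),
    )


def variant_odds_ratio(
    case_ac: int,
    case_an: int,
    panel_ac: int,
    panel_an: int,
    unit: object = None,
    panel: str = "",
) -> AssociationResult:
    """Per-variant association: OR (Haldane-corrected on zero cells), Woolf
    95% CI, one-sided Fisher p (m = 1, so p_corrected = p)."""
    table = ContingencyTable(case_ac, case_an - case_ac, panel_ac, panel_an - panel_ac)
    or_point, lo, hi = odds_ratio_ci(table)
    p = fisher_one_sided(table)
    note = None
    if math.isnan(or_point):
        note = "no alternate alleles in cases or panel; OR undefined"
    return AssociationResult(
        unit=unit,
        panel=panel,
        or_point=or_point,
        ci_low=lo,
        ci_high=hi,
        p=p,
        p_corrected=bonferroni_correct(p, 1),
        m=1,
        note=note,
    )


def aggregate_gene_table(
    records: Sequence[VariantRecord],
    case_n: int,
    panel: ReferencePanel,
    drop_missing: bool = False,
) -> tuple[ContingencyTable, int]:
    """Sum per-variant allele counts for one gene into a single 2x2 table.

    Cases contribute the QC-passing pooled alternate count per variant
    against 2 x case_n alleles; the panel contributes its AC/AN.  Variants
    absent from the panel contribute AC = 0 with the panel's full AN
    (``drop_missing=True`` excludes them from that panel's table instead).
    """
    if not records:
        raise ValidationError("no variants to aggregate for this gene")
    case_an_per_variant = 2 * case_n
    a = b = c = d = 0
    m = 0
    for rec in records:
        entry = panel.freqs.get(rec.key)
        if entry is None:
            if drop_missing:
                continue
            entry = (0, 2 * panel.n_individuals)
        ac = rec.case_alt_count()
        a += ac
        b += case_an_per_variant - ac
        c += entry[0]
        d += entry[1] - entry[0]
        m += 1
    if m == 0:
        raise ValidationError("all variants missing from panel and drop_missing set")
    return ContingencyTable(a, b, c, d), m


class GeneBurdenModel:
    """Per-gene allele-count burden test against reference panels.

    Parameters
    ----------
    records
        Cascade-filtered variant records (annotated, MAF-thresholded).
        Records without a gene assignment are ignored.
    panels
        Mapping of panel name to :class:`ReferencePanel`; each requested
        panel yields one association per gene.
    case_n
        Number of diploid case individuals (case allele total is 2 x case_n
        per variant).
    spanish_panel
        Name of the panel used for the "described in the Spanish population"
        restriction of the secondary analysis.
    """

    def __init__(
        self,
        records: Sequence[VariantRecord],
        panels: Mapping[str, ReferencePanel] | Iterable[ReferencePanel],
        case_n: int,
        spanish_panel: str = "spanish",
    ) -> None:
        if not isinstance(panels, Mapping):
            panels = {p.name: p for p in panels}
        if not panels:
            raise ConfigurationError("at least one reference panel is required")
        if case_n <= 0:
            raise ConfigurationError("case_n must be positive")
        self.records = list(records)
        self.panels = dict(panels)
        self.case_n = case_n
        self.spanish_panel = spanish_panel
        self._by_gene: dict[str, list[VariantRecord]] = {}
        for rec in self.records:
            if rec.gene is not None:
                self._by_gene.setdefault(rec.gene, []).append(rec)

    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def _restricted(self, group: list[VariantRecord]) -> list[VariantRecord]:
        panel = self.panels.get(self.spanish_panel)
        if panel is None:
            raise ConfigurationError(
                f"restriction requires panel {self.spanish_panel!r}; "
                f"available: {sorted(self.panels)}"
            )
        return [
            r
            for r in group
            if r.functional_class == "missense"
            and r.key in panel
            and panel.freqs[r.key][0] > 0
        ]

    def fit(
        self,
        restrict_to_described_missense: bool = False,
        drop_missing: bool = False,
        alpha: float = 0.05,
    ) -> "GeneBurdenResults":
        """Run the burden test for every gene and panel.

        With ``restrict_to_described_missense`` the secondary analysis is
        performed: only missense variants with a present, non-zero entry in
        the Spanish-like panel enter the tables, and ``percent_retained``
        reports the retained fraction of the unrestricted variant count.
        The Bonferroni multiplier is always the m of the analysis actually
        run.
        """
        rows = []
        skipped: list[str] = []
        for gene in self.genes():
            group = self._by_gene[gene]
            m_total = len(group)
            used = self._restricted(group) if restrict_to_described_missense else group
            if not used:
                skipped.append(gene)
                continue
            for panel_name, panel in sorted(self.panels.items()):
                table, m = aggregate_gene_table(
                    used, self.case_n, panel, drop_missing=drop_missing
                )
                or_point, lo, hi = odds_ratio_ci(table)
                p = fisher_one_sided(table)
                row = {
                    "gene": gene,
                    "panel": panel_name,
                    "m": m,
                    "case_ac": table.a,
                    "case_an": table.a + table.b,
                    "panel_ac": table.c,
                    "panel_an": table.c + table.d,
                    "odds_ratio": or_point,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": p,
                    "p_corrected": bonferroni_correct(p, m),
                }
                if restrict_to_described_missense:
                    row["m_unrestricted"] = m_total
                    row["percent_retained"] = 100.0 * len(used) / m_total
                rows.append(row)
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame = frame.sort_values(["gene", "panel"], kind="stable").reset_index(
                drop=True
            )
        return GeneBurdenResults(
            model=self,
            frame=frame,
            restricted=restrict_to_described_missense,
            alpha=alpha,
            skipped_genes=skipped,
        )


@dataclass
class GeneBurdenResults:
    """Fitted burden analysis: one row per gene x panel in ``frame``."""

    model: GeneBurdenModel
    frame: pd.DataFrame
    restricted: bool
    alpha: float
    skipped_genes: list[str]

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.alpha if alpha is None else alpha
        if self.frame.empty:
            return self.frame
        return self.frame[self.frame["p_corrected"] < alpha]

    def gene_panel(self, gene: str, panel: str) -> pd.Series:
        hit = self.frame[(self.frame["gene"] == gene) & (self.frame["panel"] == panel)]
        if hit.empty:
            raise KeyError(f"no result for gene {gene!r} panel {panel!r}")
        return hit.iloc[0]

    def summary(self) -> str:
        """Human-readable table: OR (CI) to 2 decimals, p-values in
        3-significant-digit scientific notation."""
        title = (
            "Gene burden analysis (missense described in Spanish panel)"
            if self.restricted
            else "Gene burden analysis (all exonic variants)"
        )
        lines = [title, "=" * len(title)]
        if self.frame.empty:
            lines.append("(no genes)")
            return "\n".join(lines)
        disp = self.frame.copy()
        disp["OR (95% CI)"] = [
            "NA"
            if np.isnan(o)
            else f"{o:.2f} ({lo:.2f}-{hi:.2f})"
            for o, lo, hi in zip(disp["odds_ratio"], disp["ci_low"], disp["ci_high"])
        ]
        disp["P value"] = [f"{p:.2E}" for p in disp["p_value"]]
        disp["P corrected"] = [f"{p:.2E}" for p in disp["p_corrected"]]
        cols = ["gene", "panel", "m", "OR (95% CI)", "P value", "P corrected"]
        if self.restricted:
            disp["% retained"] = [f"{x:.0f}" for x in disp["percent_retained"]]
            cols.insert(3, "% retained")
        lines.append(disp[cols].to_string(index=False))
        if self.skipped_genes:
            lines.append(
                f"skipped (no qualifying variants): {', '.join(self.skipped_genes)}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_burden_analysis(
    records: Sequence[VariantRecord],
    panels: Mapping[str, ReferencePanel] | Iterable[ReferencePanel],
    case_n: int,
    restrict_to_described_missense: bool = False,
    spanish_panel: str = "spanish",
) -> GeneBurdenResults:
    """Functional wrapper over :class:`GeneBurdenModel` + ``fit``."""
    model = GeneBurdenModel(records, panels, case_n, spanish_panel=spanish_panel)
    return model.fit(restrict_to_described_missense=restrict_to_described_missense)


def prioritize_rare_variants(
    records: Sequence[VariantRecord],
    case_n: int,
    panels: Mapping[str, ReferencePanel] | Iterable[ReferencePanel],
    maf_cut: float = 0.001,
    cadd_cut: float | None = None,
) -> pd.DataFrame:
    """Rank rare variants by deleteriousness.

    A variant qualifies when every panel frequency available for it is below
    ``maf_cut``; variants absent from every panel are kept and flagged novel.
    Ranking is by descending CADD phred (missing CADD last), ties broken by
    (chrom, pos, alt).  ``cadd_cut`` (optional) truncates to variants with
    CADD >= the cut.
    """
    if not isinstance(panels, Mapping):
        panels = {p.name: p for p in panels}
    if not 0.0 < maf_cut <= 1.0:
        raise ConfigurationError(f"maf_cut must lie in (0, 1], got {maf_cut}")
    rows = []
    for rec in records:
        afs = {name: panel.af(rec.key) for name, panel in panels.items()}
        present = {name: af for name, af in afs.items() if af is not None}
        if present and max(present.values()) >= maf_cut:
            continue
        row = {
            "chrom": rec.key.chrom,
            "pos": rec.key.pos,
            "ref": rec.key.ref,
            "alt": rec.key.alt,
            "gene": rec.gene,
            "functional_class": rec.functional_class,
            "dbsnp_id": rec.dbsnp_id,
            "cohort_maf": cohort_maf(rec.case_alt_count(), case_n),
            "cadd_phred": rec.cadd_phred,
            "novel": not present,
        }
        for name in sorted(panels):
            row[f"maf_{name}"] = afs[name]
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    if cadd_cut is not None:
        frame = frame[frame["cadd_phred"].notna() & (frame["cadd_phred"] >= cadd_cut)]
    frame = frame.assign(
        _rank=pd.to_numeric(frame["cadd_phred"], errors="coerce").fillna(-np.inf)
    )
    frame = frame.sort_values(
        ["_rank", "chrom", "pos", "alt"],
        ascending=[False, True, True, True],
        kind="stable",
    ).drop(columns="_rank")
    return frame.reset_index(drop=True)
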