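"""Validation experiments: Fisher-oracle agreement, burden power/type-I,
filter artifact targeting.

These drive the package's own quality checks: the one-sided Fisher
implementation is compared against an exact integer enumeration oracle, and
the full simulate-filter-test pipeline is replicated to measure detection of
enriched genes and the false-positive rate on null genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .burden import GeneBurdenModel, fisher_one_sided
from .filters import (
    FilterLedger,
    functional_class_filter,
    maf_threshold_filter,
    site_quality_filter,
    strand_bias_filter,
)
from .simulate import CohortConfig, SimulatedCohort, simulate_cohort
from .variants import VariantRecord


def fisher_tail_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p by brute-force enumeration.

    Sums exact integer binomial-coefficient products C(K, k) * C(N-K, n-k)
    over every table at least as enriched as observed (k >= a) with the
    margins fixed, and divides by C(N, n).  Independent of the survival-
    function implementation it serves as an oracle for.
    """
    total = a + b + c + d
    if total == 0:
        return 1.0
    n_case = a + b
    k_alt = a + c
    numerator = 0
    for k in range(a, min(k_alt, n_case) + 1):
        numerator += math.comb(k_alt, k) * math.comb(total - k_alt, n_case - k)
    return numerator / math.comb(total, n_case)


def _enumerated_tails(total: int, k_alt: int, n_case: int) -> list[float]:
    """Exact upper-tail probabilities P(X >= a) for all feasible a, by
    suffix-summing integer binomial-coefficient products."""
    lo = max(0, k_alt + n_case - total)
    hi = min(k_alt, n_case)
    weights = [
        math.comb(k_alt, k) * math.comb(total - k_alt, n_case - k)
        for k in range(lo, hi + 1)
    ]
    denom = math.comb(total, n_case)
    tails = [0.0] * (hi - lo + 1)
    acc = 0
    for i in range(len(weights) - 1, -1, -1):
        acc += weights[i]
        tails[i] = acc / denom
    return tails  # tails[i] = P(X >= lo + i)


@dataclass
class FisherAgreement:
    n_checked: int
    max_abs_diff: float


def fisher_enumeration_agreement(
    max_total: int = 60,
    n_random: int = 2000,
    random_max_total: int = 200,
    seed: int = 0,
) -> FisherAgreement:
    """Compare the Fisher implementation with the enumeration oracle.

    Exhaustive over every 2x2 table with grand total <= ``max_total`` (every
    feasible ``a`` for every margin configuration), plus ``n_random`` seeded
    random tables with grand totals up to ``random_max_total``.
    """
    n_checked = 0
    max_diff = 0.0
    for total in range(0, max_total + 1):
        for k_alt in range(0, total + 1):
            for n_case in range(0, total + 1):
                lo = max(0, k_alt + n_case - total)
                tails = _enumerated_tails(total, k_alt, n_case)
                for i, expected in enumerate(tails):
                    a = lo + i
                    b = n_case - a
                    c = k_alt - a
                    d = total - a - b - c
                    p = fisher_one_sided((a, b, c, d))
                    max_diff = max(max_diff, abs(p - expected))
                    n_checked += 1
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        total = int(rng.integers(max_total + 1, random_max_total + 1))
        k_alt = int(rng.integers(0, total + 1))
        n_case = int(rng.integers(0, total + 1))
        lo = max(0, k_alt + n_case - total)
        hi = min(k_alt, n_case)
        a = int(rng.integers(lo, hi + 1))
        expected = fisher_tail_by_enumeration(
            a, n_case - a, k_alt - a, total - k_alt - n_case + a
        )
        p = fisher_one_sided((a, n_case - a, k_alt - a, total - k_alt - n_case + a))
        max_diff = max(max_diff, abs(p - expected))
        n_checked += 1
    return FisherAgreement(n_checked=n_checked, max_abs_diff=max_diff)


def annotate_from_sites(
    records: Sequence[VariantRecord], cohort: SimulatedCohort
) -> list[VariantRecord]:
    """Attach gene/class/CADD annotations to records directly from the
    simulator's site table (in-memory equivalent of the annotation TSV join)."""
    table = {
        key: row
        for key, row in zip(
            cohort.truth.keys(), cohort.sites.itertuples(index=False)
        )
    }
    for rec in records:
        row = table.get(rec.key)
        if row is not None:
            rec.gene = row.gene
            rec.functional_class = row.functional_class
            rec.cadd_phred = None if row.cadd_phred is None else float(row.cadd_phred)
            rec.dbsnp_id = row.dbsnp_id
    return list(records)


@dataclass
class PowerResult:
    """Detection and false-positive rates of the burden test over replicated
    synthetic cohorts (rates in percent)."""

    n_replicates: int
    n_enriched_tests: int
    n_null_tests: int
    enriched_detection_rate: float
    null_significant_rate: float


def burden_power_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    inflation: float = 5.0,
    n_enriched_genes: int = 3,
    n_null_genes: int = 3,
    variants_per_gene: int = 5,
    n_cases: int = 830,
    n_controls: int = 40,
    test_panel: str = "spanish",
    alpha: float = 0.05,
) -> PowerResult:
    """Replicate the full simulate -> QC -> burden pipeline and measure how
    often enriched genes reach Bonferroni-corrected p < alpha on the test
    panel, and how often null genes do.

    Panels are fully described (no Spanish-missing variants) so the
    case-vs-panel comparison is calibrated; artifacts are off.
    """
    n_genes = n_enriched_genes + n_null_genes
    enriched = {f"G{i:03d}": inflation for i in range(n_enriched_genes)}
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    n_enriched_hits = n_null_hits = 0
    n_enriched_tests = n_null_tests = 0
    for rep_seed in seeds:
        cfg = CohortConfig(
            n_cases=n_cases,
            n_controls=n_controls,
            n_genes=n_genes,
            variants_per_gene=variants_per_gene,
            enriched_genes=enriched,
            spanish_missing_rate=0.0,
            seed=int(rep_seed),
        )
        sim = simulate_cohort(cfg)
        records = annotate_from_sites(sim.records, sim)
        ledger = FilterLedger()
        records = site_quality_filter(records, ledger=ledger)
        records = strand_bias_filter(records, ledger=ledger)
        records = functional_class_filter(records, ledger=ledger)
        records = maf_threshold_filter(
            records, sim.panels["global"], 0.1, ledger=ledger
        )
        results = GeneBurdenModel(records, sim.panels, cfg.n_cases).fit()
        frame = results.frame
        frame = frame[frame["panel"] == test_panel]
        for row in frame.itertuples(index=False):
            hit = row.p_corrected < alpha
            if row.gene in enriched:
                n_enriched_tests += 1
                n_enriched_hits += hit
            else:
                n_null_tests += 1
                n_null_hits += hit
    return PowerResult(
        n_replicates=n_replicates,
        n_enriched_tests=n_enriched_tests,
        n_null_tests=n_null_tests,
        enriched_detection_rate=100.0 * n_enriched_hits / max(n_enriched_tests, 1),
        null_significant_rate=100.0 * n_null_hits / max(n_null_tests, 1),
    )


@dataclass
class ArtifactTargeting:
    """Where each injected artifact class was removed in the cascade."""

    n_injected: dict[str, int]
    n_removed_at_target: dict[str, int]
    clean_false_removals: int

    @property
    def all_on_target(self) -> bool:
        return (
            self.n_injected == self.n_removed_at_target
            and self.clean_false_removals == 0
        )

    @property
    def accuracy_percent(self) -> float:
        total = sum(self.n_injected.values())
        if total == 0:
            return 100.0
        return 100.0 * sum(self.n_removed_at_target.values()) / total


_TARGET_STAGE = {
    "single_strand": "strand_bias",
    "low_depth": "site_quality",
    "low_gq": "site_quality",
}


def artifact_targeting_experiment(
    seed: int = 0,
    n_genes: int = 20,
    variants_per_gene: int = 10,
    artifact_rate: float = 0.08,
) -> ArtifactTargeting:
    """Simulate with artifacts on, run QC + strand filters, and verify each
    injected artifact site is removed by exactly the stage targeting it and
    that no clean site is removed by either stage."""
    cfg = CohortConfig(
        n_cases=200,
        n_controls=20,
        n_genes=n_genes,
        variants_per_gene=variants_per_gene,
        af_range=(2e-3, 0.05),
        artifact_rates={cls: artifact_rate for cls in _TARGET_STAGE},
        seed=seed,
    )
    sim = simulate_cohort(cfg)
    artifact_keys = sim.truth.artifact_keys()
    all_artifacts = set().union(*artifact_keys.values())
    # control-only variants are removed at QC by design (no case support);
    # they are not clean-site false removals
    case_supported = {
        r.key
        for r in sim.records
        if any(o.alt_count > 0 for o in r.pools if not o.is_control_pool)
    }

    ledger = FilterLedger()
    records = site_quality_filter(sim.records, ledger=ledger)
    records = strand_bias_filter(records, ledger=ledger)

    n_injected = {}
    n_on_target = {}
    for cls, keys in artifact_keys.items():
        # only sites that made it into the call set count
        called = keys & {r.key for r in sim.records}
        removed_here = ledger.removed_at(_TARGET_STAGE[cls])
        n_injected[cls] = len(called)
        n_on_target[cls] = len(called & removed_here)
    clean_removed = (
        (ledger.removed_at("site_quality") | ledger.removed_at("strand_bias"))
        & case_supported
    ) - all_artifacts
    return ArtifactTargeting(
        n_injected=n_injected,
        n_removed_at_target=n_on_target,
        clean_false_removals=len(clean_removed),
    )
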