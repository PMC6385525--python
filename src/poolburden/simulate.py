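"""Synthetic pooled-sequencing cohorts with matching reference panels.

The generator emulates the study design the pipeline expects: a large case
cohort and a small control group of diploid individuals, sequenced in pools
of ``pool_size`` (a pool of 10 diploids is one sample of ploidy 20) on a
targeted gene panel at ~250X, compared against three population
allele-frequency panels (a global exome panel, its non-Finnish European
subset, and a smaller Spanish-population panel).

Genotypes are drawn under Hardy-Weinberg at a per-variant population allele
frequency; designated "enriched" genes have their case allele frequencies
multiplied by a configurable inflation factor.  Pool calling is the true
member allele count perturbed only through read sampling (binomial reads at
the pool allele fraction plus a per-read error rate, symmetric strand split,
negative-binomial depth).  Artifact sites — single-strand calls, low-depth
sites, low-GQ sites — are injected at configurable rates so the filter
cascade has ground truth to be tested against.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import CASE_POOL_PREFIX, CONTROL_POOL_PREFIX
from .variants import PoolObservation, ReferencePanel, VariantKey, VariantRecord

ARTIFACT_CLASSES = ("single_strand", "low_depth", "low_gq")

#: Default panel cohort sizes: global exome panel, non-Finnish European
#: subset, Spanish population panel.
DEFAULT_PANEL_SIZES = {"global": 60706, "nfe": 33370, "spanish": 1579}

_CLASS_PROBS = {
    "missense": 0.68,
    "synonymous": 0.275,
    "stopgain": 0.015,
    "stoploss": 0.005,
    "other": 0.025,
}


def n_pools(n_individuals: int, pool_size: int) -> int:
    """Number of pools for a cohort (errors unless pool_size divides it)."""
    if pool_size <= 0:
        raise ConfigurationError(f"pool_size must be positive, got {pool_size}")
    if n_individuals % pool_size:
        raise ConfigurationError(
            f"{n_individuals} individuals cannot be split into pools of {pool_size}"
        )
    return n_individuals // pool_size


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions
    (830 sporadic cases, 40 controls, pools of 10, 69-gene panel, 250X)."""

    n_cases: int = 830
    n_controls: int = 40
    pool_size: int = 10
    n_genes: int = 69
    #: variants per gene: an int, or an inclusive (low, high) range
    variants_per_gene: int | tuple[int, int] = 14
    #: log-uniform allele-frequency law on [low, high) for panel variants
    af_range: tuple[float, float] = (2e-4, 0.05)
    #: gene name -> case allele-frequency inflation factor (>= 1)
    enriched_genes: dict[str, float] = field(default_factory=dict)
    mean_depth: float = 250.0
    #: negative-binomial dispersion (size parameter k); larger = tighter
    depth_dispersion: float = 10.0
    #: per-read probability of reading the wrong allele
    read_error_rate: float = 1e-3
    #: per-site probabilities of each injected artifact class
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {"single_strand": 0.0, "low_depth": 0.0, "low_gq": 0.0}
    )
    #: fraction of variants absent from the Spanish-like panel
    spanish_missing_rate: float = 0.1
    panel_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_SIZES)
    )
    #: "binomial" draws panel AC ~ Bin(AN, af); "expected" rounds af * AN
    ac_sampling: str = "binomial"
    seed: int = 0

    @property
    def ploidy(self) -> int:
        return 2 * self.pool_size

    def gene_names(self) -> list[str]:
        return [f"G{i:03d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.pool_size <= 0:
            raise ConfigurationError("pool_size must be positive")
        for label, n in (("n_cases", self.n_cases), ("n_controls", self.n_controls)):
            if n < 0 or n % self.pool_size:
                raise ConfigurationError(
                    f"{label} = {n} is not a non-negative multiple of pool_size "
                    f"{self.pool_size}"
                )
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        vpg = self.variants_per_gene
        if isinstance(vpg, int):
            ok = vpg > 0
        else:
            ok = len(vpg) == 2 and 0 < vpg[0] <= vpg[1]
        if not ok:
            raise ConfigurationError(f"invalid variants_per_gene: {vpg!r}")
        lo, hi = self.af_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(f"af_range must satisfy 0 < low <= high < 1, got {self.af_range}")
        genes = set(self.gene_names())
        for gene, factor in self.enriched_genes.items():
            if gene not in genes:
                raise ConfigurationError(f"enriched gene {gene!r} is not in the panel")
            if factor < 1.0:
                raise ConfigurationError(
                    f"inflation factor for {gene} must be >= 1, got {factor}"
                )
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ConfigurationError("mean_depth and depth_dispersion must be positive")
        if not 0.0 <= self.read_error_rate < 0.5:
            raise ConfigurationError("read_error_rate must lie in [0, 0.5)")
        for cls, rate in self.artifact_rates.items():
            if cls not in ARTIFACT_CLASSES:
                raise ConfigurationError(f"unknown artifact class {cls!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"artifact rate for {cls} outside [0, 1]")
        if sum(self.artifact_rates.values()) > 1.0:
            raise ConfigurationError("artifact rates sum to more than 1")
        if not 0.0 <= self.spanish_missing_rate <= 1.0:
            raise ConfigurationError("spanish_missing_rate outside [0, 1]")
        for name, size in self.panel_sizes.items():
            if size <= 0:
                raise ConfigurationError(f"panel {name} has non-positive size")
        if self.ac_sampling not in ("binomial", "expected"):
            raise ConfigurationError(f"unknown ac_sampling {self.ac_sampling!r}")


def _streams(config: CohortConfig) -> dict[str, np.random.Generator]:
    """Independent seeded substreams so each stage is deterministic on its own."""
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("sites", "panels", "genotypes", "calling")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def simulate_sites(config: CohortConfig) -> pd.DataFrame:
    """Draw the variant sites of the panel: positions, alleles, generating
    allele frequency, gene, functional class, CADD phred, dbSNP id, and
    whether the site is represented in the Spanish-like panel."""
    config.validate()
    rng = _streams(config)["sites"]
    genes = config.gene_names()
    vpg = config.variants_per_gene
    rows = []
    bases = np.array(list("ACGT"))
    classes = list(_CLASS_PROBS)
    class_p = np.array([_CLASS_PROBS[c] for c in classes])
    lo, hi = config.af_range
    for g_index, gene in enumerate(genes):
        chrom = f"chr{(g_index % 22) + 1}"
        base_pos = 1_000_000 * (g_index + 1)
        count = (
            vpg
            if isinstance(vpg, int)
            else int(rng.integers(vpg[0], vpg[1] + 1))
        )
        for v in range(count):
            ref, alt = rng.choice(bases, size=2, replace=False)
            if lo == hi:
                af = lo
            else:
                af = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            fclass = classes[int(rng.choice(len(classes), p=class_p))]
            cadd_missing_p = 0.85 if fclass == "synonymous" else 0.1
            cadd = (
                None
                if rng.random() < cadd_missing_p
                else round(float(rng.uniform(0.01, 40.0)), 3)
            )
            dbsnp = (
                f"rs{int(rng.integers(10_000, 200_000_000))}"
                if rng.random() < 0.5
                else None
            )
            rows.append(
                {
                    "chrom": chrom,
                    "pos": base_pos + 3 * v,
                    "ref": str(ref),
                    "alt": str(alt),
                    "gene": gene,
                    "true_af": af,
                    "functional_class": fclass,
                    "cadd_phred": cadd,
                    "dbsnp_id": dbsnp,
                    "in_spanish": bool(rng.random() >= config.spanish_missing_rate),
                }
            )
    return pd.DataFrame(rows)


def _site_keys(sites: pd.DataFrame) -> list[VariantKey]:
    return [
        VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in sites.itertuples(index=False)
    ]


def simulate_reference_panels(
    config: CohortConfig, sites: pd.DataFrame | None = None
) -> dict[str, ReferencePanel]:
    """Build the reference panels around the generating allele frequencies.

    Every panel shares the generating AF (the panels describe the same
    ancestral population); AN = 2N everywhere; a configurable fraction of
    variants is absent from the Spanish-like panel.
    """
    config.validate()
    if sites is None:
        sites = simulate_sites(config)
    rng = _streams(config)["panels"]
    keys = _site_keys(sites)
    afs = sites["true_af"].to_numpy()
    in_spanish = sites["in_spanish"].to_numpy()
    panels: dict[str, ReferencePanel] = {}
    for name, n_ind in config.panel_sizes.items():
        an = 2 * n_ind
        if config.ac_sampling == "binomial":
            acs = rng.binomial(an, afs)
        else:
            acs = np.rint(afs * an).astype(int)
        freqs = {}
        for i, key in enumerate(keys):
            if name == "spanish" and not in_spanish[i]:
                continue
            freqs[key] = (int(acs[i]), an)
        panels[name] = ReferencePanel(name=name, n_individuals=n_ind, freqs=freqs)
    return panels


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated cohort, for parameter-recovery tests."""

    sites: pd.DataFrame
    case_genotypes: np.ndarray  # (n_cases, n_variants), values 0/1/2
    control_genotypes: np.ndarray  # (n_controls, n_variants)
    enriched_genes: dict[str, float]
    #: artifact class -> sorted site row indices; classes are disjoint
    artifact_sites: dict[str, list[int]]
    #: panel name -> per-site true AF (NaN where absent from the panel)
    panel_afs: dict[str, np.ndarray]

    def keys(self) -> list[VariantKey]:
        return _site_keys(self.sites)

    def artifact_keys(self) -> dict[str, set[VariantKey]]:
        keys = self.keys()
        return {
            cls: {keys[i] for i in idx} for cls, idx in self.artifact_sites.items()
        }

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "sites": self.sites.where(pd.notna(self.sites), None).to_dict("records"),
            "case_genotypes": self.case_genotypes.tolist(),
            "control_genotypes": self.control_genotypes.tolist(),
            "enriched_genes": self.enriched_genes,
            "artifact_sites": self.artifact_sites,
            "panel_afs": {k: list(v) for k, v in self.panel_afs.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimulatedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            sites=pd.DataFrame(payload["sites"]),
            case_genotypes=np.asarray(payload["case_genotypes"], dtype=int),
            control_genotypes=np.asarray(payload["control_genotypes"], dtype=int),
            enriched_genes=payload["enriched_genes"],
            artifact_sites={k: list(v) for k, v in payload["artifact_sites"].items()},
            panel_afs={k: np.asarray(v) for k, v in payload["panel_afs"].items()},
        )


def simulate_genotypes(
    config: CohortConfig, sites: pd.DataFrame | None = None
) -> SimulatedTruth:
    """Draw Hardy-Weinberg genotypes for cases and controls.

    Case allele frequencies are multiplied by the configured inflation factor
    in enriched genes; an inflated frequency above 1 raises
    :class:`ConfigurationError` (clamping would silently change the design).
    Artifact sites are selected here (among variants actually carried by at
    least one case) and recorded in the truth object; the pooled caller
    applies them.
    """
    config.validate()
    if sites is None:
        sites = simulate_sites(config)
    rng = _streams(config)["genotypes"]
    afs = sites["true_af"].to_numpy()
    inflation = sites["gene"].map(lambda g: config.enriched_genes.get(g, 1.0)).to_numpy()
    case_afs = afs * inflation
    too_high = case_afs > 1.0
    if np.any(too_high):
        i = int(np.argmax(too_high))
        raise ConfigurationError(
            f"inflated allele frequency {case_afs[i]:.4f} exceeds 1 for gene "
            f"{sites['gene'].iloc[i]} (af {afs[i]:.4f} x factor {inflation[i]:g})"
        )
    n_var = len(sites)
    case_gt = rng.binomial(2, case_afs, size=(config.n_cases, n_var)).astype(np.int64)
    control_gt = rng.binomial(2, afs, size=(config.n_controls, n_var)).astype(np.int64)

    carried = case_gt.sum(axis=0) > 0
    artifact_sites: dict[str, list[int]] = {cls: [] for cls in ARTIFACT_CLASSES}
    rates = [config.artifact_rates.get(cls, 0.0) for cls in ARTIFACT_CLASSES]
    if any(rates):
        u = rng.random(n_var)
        edges = np.cumsum(rates)
        for i in range(n_var):
            if not carried[i]:
                continue
            for cls, edge in zip(ARTIFACT_CLASSES, edges):
                if u[i] < edge:
                    artifact_sites[cls].append(i)
                    break

    in_spanish = sites["in_spanish"].to_numpy()
    panel_afs = {}
    for name in config.panel_sizes:
        values = afs.astype(float).copy()
        if name == "spanish":
            values[~in_spanish] = np.nan
        panel_afs[name] = values

    return SimulatedTruth(
        sites=sites,
        case_genotypes=case_gt,
        control_genotypes=control_gt,
        enriched_genes=dict(config.enriched_genes),
        artifact_sites=artifact_sites,
        panel_afs=panel_afs,
    )


def pool_and_call(truth: SimulatedTruth, config: CohortConfig) -> list[VariantRecord]:
    """Pool genotypes and synthesise per-pool calls.

    Per pool and variant the called alternate count is the exact member
    allele sum (0..ploidy); reads are drawn binomially at the pool allele
    fraction with the per-read error rate folded in, split symmetrically
    across strands; GQ is high for clean sites.  Injected artifact sites
    overwrite these fields for every pool of the site:

    * ``single_strand`` — all alternate reads moved to the forward strand;
    * ``low_depth``     — depth redrawn uniformly in [1, 9], reads redrawn;
    * ``low_gq``        — GQ redrawn uniformly in [0, 19].

    Only variants called (alt count > 0) in at least one pool are emitted.
    """
    config.validate()
    rng = _streams(config)["calling"]
    ploidy = config.ploidy
    n_case_pools = n_pools(config.n_cases, config.pool_size)
    n_ctrl_pools = n_pools(config.n_controls, config.pool_size)
    n_var = len(truth.sites)

    def pool_counts(gt: np.ndarray, n_p: int) -> np.ndarray:
        if n_p == 0:
            return np.zeros((0, n_var), dtype=np.int64)
        return gt.reshape(n_p, config.pool_size, n_var).sum(axis=1)

    alt = np.vstack(
        [
            pool_counts(truth.case_genotypes, n_case_pools),
            pool_counts(truth.control_genotypes, n_ctrl_pools),
        ]
    )
    total_pools = n_case_pools + n_ctrl_pools
    pool_ids = [f"{CASE_POOL_PREFIX}{i:03d}" for i in range(n_case_pools)] + [
        f"{CONTROL_POOL_PREFIX}{i:02d}" for i in range(n_ctrl_pools)
    ]
    is_control = [False] * n_case_pools + [True] * n_ctrl_pools

    k = config.depth_dispersion
    p_nb = k / (k + config.mean_depth)
    depth = rng.negative_binomial(k, p_nb, size=(total_pools, n_var))
    e = config.read_error_rate
    frac = alt / ploidy
    p_read = frac * (1.0 - e) + (1.0 - frac) * e
    alt_reads = rng.binomial(depth, p_read)
    fwd = rng.binomial(alt_reads, 0.5)
    rev = alt_reads - fwd
    gq = np.full((total_pools, n_var), 99, dtype=np.int64)

    for i in truth.artifact_sites.get("low_depth", []):
        depth[:, i] = rng.integers(1, 10, size=total_pools)
        alt_reads[:, i] = rng.binomial(depth[:, i], p_read[:, i])
        fwd[:, i] = rng.binomial(alt_reads[:, i], 0.5)
        rev[:, i] = alt_reads[:, i] - fwd[:, i]
    for i in truth.artifact_sites.get("low_gq", []):
        gq[:, i] = rng.integers(0, 20, size=total_pools)
    for i in truth.artifact_sites.get("single_strand", []):
        fwd[:, i] = alt_reads[:, i]
        rev[:, i] = 0

    keys = truth.keys()
    records: list[VariantRecord] = []
    called = alt.sum(axis=0) > 0
    for v in range(n_var):
        if not called[v]:
            continue
        pools = [
            PoolObservation(
                pool_id=pool_ids[p],
                alt_count=int(alt[p, v]),
                depth=int(depth[p, v]),
                gq=int(gq[p, v]),
                fwd_alt=int(fwd[p, v]),
                rev_alt=int(rev[p, v]),
                ploidy=ploidy,
                is_control_pool=is_control[p],
            )
            for p in range(total_pools)
        ]
        records.append(VariantRecord(key=keys[v], pools=pools))
    return records


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulation produced."""

    config: CohortConfig
    sites: pd.DataFrame
    panels: dict[str, ReferencePanel]
    truth: SimulatedTruth
    records: list[VariantRecord]

    def annotations(self) -> pd.DataFrame:
        frame = self.sites.loc[
            :,
            ["chrom", "pos", "ref", "alt", "gene", "functional_class", "cadd_phred", "dbsnp_id"],
        ].copy()
        return frame


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Run the full generator: sites, panels, genotypes, pooled calls."""
    config.validate()
    sites = simulate_sites(config)
    panels = simulate_reference_panels(config, sites)
    truth = simulate_genotypes(config, sites)
    records = pool_and_call(truth, config)
    return SimulatedCohort(
        config=config, sites=sites, panels=panels, truth=truth, records=records
    )


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
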