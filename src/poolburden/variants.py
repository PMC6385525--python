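"""Core variant data types and key normalisation.

Every stage of the pipeline keys records by a normalised biallelic
:class:`VariantKey` (1-based VCF coordinates, one alternate allele per key;
multi-allelic sites are split upstream).  A :class:`VariantRecord` carries one
pool-level observation per sequenced pool — a pool of ``k`` diploid
individuals behaves as a single sample of ploidy ``2k`` — plus the gene-level
annotations and reference-panel frequencies the burden analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ValidationError, VariantError

_BASES = frozenset("ACGT")

#: Functional classes accepted at annotation time.  The exonic set used by the
#: class filter is the first four; ``other`` covers UTR/flanking calls that a
#: capture design with flanking bait coverage produces.
FUNCTIONAL_CLASSES = ("missense", "synonymous", "stopgain", "stoploss", "other")
EXONIC_CLASSES = frozenset({"missense", "synonymous", "stopgain", "stoploss"})


@dataclass(frozen=True, order=True)
class VariantKey:
    """A normalised biallelic site: chromosome, 1-based position, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise VariantError("empty chromosome name")
        if self.pos < 1:
            raise VariantError(f"position must be 1-based and positive, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _BASES:
                raise VariantError(
                    f"allele {allele!r} is not a non-empty uppercase A/C/G/T string"
                )
        if self.ref == self.alt:
            raise VariantError(
                f"ref and alt are identical ({self.ref!r}) at {self.chrom}:{self.pos}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def normalize_variant(key: VariantKey) -> VariantKey:
    """Trim shared allele suffix, then shared prefix (advancing the position).

    This is the reference-free part of left normalisation: alleles are reduced
    to their minimal representation.  True left-alignment of indels against a
    reference genome is out of scope (no genome is shipped); see the methods
    note.  The operation is idempotent and never changes the chromosome.
    """
    ref, alt, pos = key.ref, key.alt, key.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == key.ref and alt == key.alt:
        return key
    return VariantKey(key.chrom, pos, ref, alt)


@dataclass
class PoolObservation:
    """One pool's call at one site.

    ``alt_count`` is the called number of alternate chromosomes out of
    ``ploidy`` (2 x pool size, 20 by default); ``fwd_alt``/``rev_alt`` are the
    strand-split alternate read counts; ``gq`` is a phred-like genotype
    quality.  ``qc_pass`` is flipped to False by the site-quality filter and
    honoured by every downstream stage.
    """

    pool_id: str
    alt_count: int
    depth: int
    gq: int
    fwd_alt: int
    rev_alt: int
    ploidy: int = 20
    is_control_pool: bool = False
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.ploidy:
            raise ValidationError(
                f"pool {self.pool_id}: alt_count {self.alt_count} outside [0, {self.ploidy}]"
            )
        if self.depth < 0 or self.gq < 0:
            raise ValidationError(f"pool {self.pool_id}: negative depth or GQ")
        if self.fwd_alt < 0 or self.rev_alt < 0:
            raise ValidationError(f"pool {self.pool_id}: negative strand read count")
        if self.fwd_alt + self.rev_alt > self.depth:
            raise ValidationError(
                f"pool {self.pool_id}: alt reads ({self.fwd_alt}+{self.rev_alt}) "
                f"exceed depth {self.depth}"
            )


@dataclass
class VariantRecord:
    """A normalised biallelic site with per-pool observations and annotations."""

    key: VariantKey
    pools: list[PoolObservation] = field(default_factory=list)
    gene: str | None = None
    functional_class: str | None = None
    cadd_phred: float | None = None
    dbsnp_id: str | None = None
    #: panel name -> (AC, AN)
    panel_freqs: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: panel names in which this variant has no entry (filled by the MAF filter)
    novel_in: set[str] = field(default_factory=set)

    def case_pools(self, valid_only: bool = True) -> list[PoolObservation]:
        return [
            o
            for o in self.pools
            if not o.is_control_pool and (o.qc_pass or not valid_only)
        ]

    def control_pools(self, valid_only: bool = True) -> list[PoolObservation]:
        return [
            o
            for o in self.pools
            if o.is_control_pool and (o.qc_pass or not valid_only)
        ]

    def case_alt_count(self) -> int:
        """Cohort alternate-allele count: called alt chromosomes summed over
        QC-passing case pools."""
        return sum(o.alt_count for o in self.case_pools())

    def case_strand_counts(self) -> tuple[int, int]:
        """(forward, reverse) alternate read counts summed over QC-passing case pools."""
        pools = self.case_pools()
        return (sum(o.fwd_alt for o in pools), sum(o.rev_alt for o in pools))

    def n_case_pools_with_alt(self) -> int:
        return sum(1 for o in self.case_pools() if o.alt_count > 0)


@dataclass
class ReferencePanel:
    """A named population allele-frequency table (AC/AN per variant).

    Stands in for public exome panels (a global panel, its non-Finnish
    European subset, a Spanish-population panel).  ``n_individuals`` is the
    panel cohort size N; AN <= 2N for every entry.
    """

    name: str
    n_individuals: int
    freqs: dict[VariantKey, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValidationError(f"panel {self.name}: non-positive cohort size")
        for key, (ac, an) in self.freqs.items():
            self._check_entry(key, ac, an)

    def _check_entry(self, key: VariantKey, ac: int, an: int) -> None:
        if not 0 <= ac <= an:
            raise ValidationError(f"panel {self.name} at {key}: AC {ac} > AN {an}")
        if an > 2 * self.n_individuals:
            raise ValidationError(
                f"panel {self.name} at {key}: AN {an} exceeds 2N = {2 * self.n_individuals}"
            )

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.freqs

    def af(self, key: VariantKey) -> float | None:
        """Alternate-allele frequency AC/AN, or None if the variant is absent."""
        entry = self.freqs.get(key)
        if entry is None:
            return None
        ac, an = entry
        return ac / an if an else 0.0
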