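"""Rule cascades that turn annotated somatic variant tables into CHIP calls.

Three cascades are provided:

* whole-exome CHIP filtering (rules ``R1``--``R9`` plus the 5-bp
  frameshift-cluster collapse, reported as ``C1``),
* lymphoid-driver filtering (``R1``--``R9`` plus the VAF window ``L1``
  and the missense evidence rule ``L2``),
* targeted-panel CHIP filtering (``P1``--``P8``).

Every rule is evaluated independently and *all* failed rule identifiers are
reported, so fixtures can assert per-rule behaviour; the pass verdict is the
conjunction of all applicable rules.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice", "synonymous", "other"}
)

#: Rule identifiers, in canonical reporting order.
WES_RULES = ("R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8", "R9")
LYMPHOID_RULES = WES_RULES + ("L1", "L2")
PANEL_RULES = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")

#: Synthetic rule id assigned to frameshift variants dropped by the 5-bp
#: cluster collapse (not a quality rule; keeps "pass == survives cascade").
CLUSTER_RULE = "C1"

_CODON_RE = re.compile(r"(\d+)")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One candidate somatic call with annotations and read evidence.

    Positions are 1-based (VCF convention). ``vaf`` is derived as
    ``alt_depth / total_depth``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    caller_label: str = "PASS"
    somatic_quality: float = 60.0
    germline_quality: float = 0.0
    total_depth: Optional[int] = None
    alt_depth: Optional[int] = None
    ref_fwd: Optional[int] = None
    ref_rev: Optional[int] = None
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None
    gnomad_max_pop_af: float = 0.0
    cosmic_count: int = 0
    reported_lchip: bool = False
    reported_all: bool = False
    splice_distance_bp: Optional[int] = None
    protein_change: Optional[str] = None

    @property
    def vaf(self) -> float:
        if not self.total_depth:
            return 0.0
        return self.alt_depth / self.total_depth

    @property
    def allele_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def validate(self) -> None:
        """Reject records with missing or negative read evidence.

        Raises
        ------
        ValueError
            Naming the offending field.
        """
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r} for "
                f"{self.sample_id} {self.chrom}:{self.pos}"
            )
        for name in ("total_depth", "alt_depth", "ref_fwd", "ref_rev", "alt_fwd", "alt_rev"):
            value = getattr(self, name)
            if value is None:
                raise ValueError(
                    f"missing required field {name!r} for variant "
                    f"{self.sample_id} {self.chrom}:{self.pos} {self.ref}>{self.alt}"
                )
            if value < 0:
                raise ValueError(
                    f"negative count in field {name!r} ({value}) for variant "
                    f"{self.sample_id} {self.chrom}:{self.pos} {self.ref}>{self.alt}"
                )
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.gnomad_max_pop_af <= 1.0:
            raise ValueError(f"gnomad_max_pop_af out of [0,1]: {self.gnomad_max_pop_af}")


def _codon(protein_change: str) -> Optional[int]:
    m = _CODON_RE.search(protein_change)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class GenePanel:
    """A named gene candidate list with optional hotspot exemptions.

    ``hotspot_exemptions`` holds ``(gene, change)`` pairs where ``change`` is
    either an exact protein change (``"V617F"``) or a bare codon number
    (``"882"``, exempting any substitution at that codon).
    """

    name: str
    genes: frozenset
    hotspot_exemptions: frozenset = frozenset()

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene panel must be non-empty")
        bad = {g for g, _ in self.hotspot_exemptions} - set(self.genes)
        if bad:
            raise ValueError(f"exemptions for genes outside the panel: {sorted(bad)}")

    def is_exempt(self, gene: str, protein_change: Optional[str]) -> bool:
        if protein_change is None:
            return False
        for exempt_gene, change in self.hotspot_exemptions:
            if exempt_gene != gene:
                continue
            if change == protein_change:
                return True
            if change.isdigit() and _codon(protein_change) == int(change):
                return True
        return False


@dataclass(frozen=True)
class FilterDecision:
    variant: AnnotatedVariant
    failed_rules: tuple

    def __post_init__(self):
        object.__setattr__(self, "failed_rules", tuple(self.failed_rules))

    @property
    def verdict(self) -> str:
        return "pass" if not self.failed_rules else "fail"


@dataclass(frozen=True)
class WesThresholds:
    """Numeric thresholds for the whole-exome rules (defaults per protocol)."""

    max_gnomad_af: float = 0.001
    min_somatic_quality: float = 3.0
    max_germline_quality: float = 10.0  # exclusive: germline_quality must be < this
    min_total_depth: int = 10
    min_alt_depth: int = 2
    min_strand_reads: int = 1
    max_splice_distance_bp: int = 2
    max_frameshift_cohort_freq: float = 0.0005  # strict ">" fails
    vaf_floor: Optional[float] = None  # off in WES mode by default
    lymphoid_vaf_min: float = 0.02
    lymphoid_vaf_max: float = 0.35
    lymphoid_min_cosmic: int = 3


@dataclass(frozen=True)
class PanelThresholds:
    """Numeric thresholds for the targeted-panel rules."""

    max_gnomad_af: float = 0.001
    max_cohort_freq: float = 0.01  # strict ">" fails
    min_total_depth: int = 100
    min_alt_depth: int = 2
    max_vaf: float = 0.40
    min_strand_reads: int = 1
    min_vaf: float = 0.02


def evaluate_chip_rules(
    variant: AnnotatedVariant,
    panel: GenePanel,
    cohort_frameshift_freq: float = 0.0,
    thresholds: WesThresholds = WesThresholds(),
) -> FilterDecision:
    """Apply the whole-exome CHIP rules ``R1``--``R9`` to one variant.

    ``cohort_frameshift_freq`` is the fraction of cohort samples carrying
    this frameshift allele (0 for non-frameshifts). All failed rules are
    reported; no short-circuiting.
    """
    variant.validate()
    t = thresholds
    failed = []
    if variant.gene not in panel.genes:
        failed.append("R1")
    if variant.gnomad_max_pop_af > t.max_gnomad_af and not panel.is_exempt(
        variant.gene, variant.protein_change
    ):
        failed.append("R2")
    if variant.caller_label != "PASS":
        failed.append("R3")
    if variant.somatic_quality < t.min_somatic_quality:
        failed.append("R4")
    if variant.germline_quality >= t.max_germline_quality:
        failed.append("R5")
    if variant.total_depth < t.min_total_depth or variant.alt_depth < t.min_alt_depth:
        failed.append("R6")
    if (
        min(variant.ref_fwd, variant.ref_rev) < t.min_strand_reads
        or min(variant.alt_fwd, variant.alt_rev) < t.min_strand_reads
    ):
        failed.append("R7")
    if variant.consequence == "splice":
        if variant.splice_distance_bp is None:
            logger.warning(
                "splice variant %s %s:%s lacks splice_distance_bp; failing R8 conservatively",
                variant.sample_id,
                variant.chrom,
                variant.pos,
            )
            failed.append("R8")
        elif variant.splice_distance_bp > t.max_splice_distance_bp:
            failed.append("R8")
    if variant.consequence == "frameshift" and cohort_frameshift_freq > t.max_frameshift_cohort_freq:
        failed.append("R9")
    if t.vaf_floor is not None and variant.vaf < t.vaf_floor:
        failed.append("VF")
    return FilterDecision(variant, tuple(failed))


def evaluate_lymphoid_rules(
    variant: AnnotatedVariant,
    panel: GenePanel,
    cohort_frameshift_freq: float = 0.0,
    thresholds: WesThresholds = WesThresholds(),
) -> FilterDecision:
    """``R1``--``R9`` plus the lymphoid-driver VAF window (``L1``) and
    missense evidence requirement (``L2``).

    Non-missense consequences are exempt from ``L2``.
    """
    base = evaluate_chip_rules(variant, panel, cohort_frameshift_freq, thresholds)
    failed = list(base.failed_rules)
    t = thresholds
    if not t.lymphoid_vaf_min <= variant.vaf <= t.lymphoid_vaf_max:
        failed.append("L1")
    if variant.consequence == "missense" and not (
        variant.cosmic_count >= t.lymphoid_min_cosmic
        or variant.reported_lchip
        or variant.reported_all
    ):
        failed.append("L2")
    return FilterDecision(variant, tuple(failed))


def evaluate_panel_rules(
    variant: AnnotatedVariant,
    panel: GenePanel,
    cohort_allele_freq: float = 0.0,
    thresholds: PanelThresholds = PanelThresholds(),
) -> FilterDecision:
    """Targeted-panel rules ``P1``--``P8``.

    ``cohort_allele_freq`` is the fraction of cohort samples carrying this
    allele (any consequence, unlike the WES frameshift-only rule).
    """
    variant.validate()
    t = thresholds
    failed = []
    if variant.caller_label != "PASS":
        failed.append("P1")
    if variant.gnomad_max_pop_af > t.max_gnomad_af:
        failed.append("P2")
    if cohort_allele_freq > t.max_cohort_freq:
        failed.append("P3")
    if variant.total_depth < t.min_total_depth:
        failed.append("P4")
    if variant.alt_depth < t.min_alt_depth:
        failed.append("P5")
    if variant.vaf > t.max_vaf:
        failed.append("P6")
    if (
        min(variant.ref_fwd, variant.ref_rev) < t.min_strand_reads
        or min(variant.alt_fwd, variant.alt_rev) < t.min_strand_reads
    ):
        failed.append("P7")
    if variant.vaf < t.min_vaf:
        failed.append("P8")
    return FilterDecision(variant, tuple(failed))


def collapse_frameshift_clusters(
    variants: Sequence[AnnotatedVariant], window_bp: int = 5
) -> list:
    """Collapse frameshift variants within ``window_bp`` of each other.

    Operates on one sample's variants. Frameshifts on the same chromosome
    are grouped by the transitive closure of ``|pos_i - pos_j| <= window_bp``
    and each group keeps only its highest-VAF member (ties broken by smaller
    pos, then lexicographic alt). Non-frameshift variants pass through.
    Input order is preserved among survivors.
    """
    samples = {v.sample_id for v in variants}
    if len(samples) > 1:
        raise ValueError(f"collapse_frameshift_clusters expects one sample, got {sorted(samples)}")
    keep = set()
    frameshifts = defaultdict(list)
    for i, v in enumerate(variants):
        if v.consequence == "frameshift":
            frameshifts[v.chrom].append((i, v))
        else:
            keep.add(i)
    for _, members in frameshifts.items():
        members = sorted(members, key=lambda t: t[1].pos)
        cluster = [members[0]]
        for item in members[1:]:
            if item[1].pos - cluster[-1][1].pos <= window_bp:
                cluster.append(item)
            else:
                keep.add(_best_frameshift(cluster))
                cluster = [item]
        keep.add(_best_frameshift(cluster))
    return [v for i, v in enumerate(variants) if i in keep]


def _best_frameshift(cluster) -> int:
    return max(cluster, key=lambda t: (t[1].vaf, -t[1].pos, _neg_lex(t[1].alt)))[0]


def _neg_lex(s: str):
    # max() helper: prefer lexicographically smaller alt on VAF+pos ties
    return tuple(-ord(c) for c in s)


GENE_GROUP_NAMES = ("DNMT3A", "TET2", "JAK2", "non_DNMT3A", "non_DNMT3A_non_JAK2")


@dataclass(frozen=True)
class CarrierProfile:
    """Per-participant carrier status with gene groups and max-VAF stratum."""

    sample_id: str
    carrier: bool
    variants: tuple
    max_vaf: Optional[float]
    vaf_stratum: Optional[str]  # "lt10" | "ge10" | None
    gene_groups: Mapping[str, bool]

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def build_carrier_profiles(
    decisions: Iterable[FilterDecision],
    samples: Sequence[str],
    vaf_stratum_cut: float = 0.10,
) -> list:
    """One profile per sample in ``samples`` (non-carriers included).

    Rejects duplicate passing rows for the same (sample, chrom, pos, alt).
    """
    passing = defaultdict(list)
    seen = set()
    for d in decisions:
        if d.verdict != "pass":
            continue
        v = d.variant
        key = (v.sample_id, v.chrom, v.pos, v.alt)
        if key in seen:
            raise ValueError(f"duplicate passing variant row for {key}")
        seen.add(key)
        passing[v.sample_id].append(v)
    profiles = []
    for sample_id in samples:
        members = tuple(sorted(passing.get(sample_id, []), key=lambda v: (v.chrom, v.pos, v.alt)))
        if members:
            max_vaf = max(v.vaf for v in members)
            genes = {v.gene for v in members}
            groups = {
                "DNMT3A": "DNMT3A" in genes,
                "TET2": "TET2" in genes,
                "JAK2": "JAK2" in genes,
                "non_DNMT3A": any(g != "DNMT3A" for g in genes),
                "non_DNMT3A_non_JAK2": any(g not in ("DNMT3A", "JAK2") for g in genes),
            }
            stratum = "lt10" if max_vaf < vaf_stratum_cut else "ge10"
            profiles.append(
                CarrierProfile(sample_id, True, members, max_vaf, stratum, groups)
            )
        else:
            profiles.append(
                CarrierProfile(
                    sample_id, False, (), None, None, {g: False for g in GENE_GROUP_NAMES}
                )
            )
    return profiles


def cohort_frameshift_frequencies(
    table: Sequence[AnnotatedVariant], n_samples: int
) -> dict:
    """Fraction of cohort samples carrying each frameshift allele."""
    carriers = defaultdict(set)
    for v in table:
        if v.consequence == "frameshift":
            carriers[v.allele_key].add(v.sample_id)
    return {k: len(s) / n_samples for k, s in carriers.items()}


def cohort_allele_frequencies(table: Sequence[AnnotatedVariant], n_samples: int) -> dict:
    """Fraction of cohort samples carrying each allele (all consequences)."""
    carriers = defaultdict(set)
    for v in table:
        carriers[v.allele_key].add(v.sample_id)
    return {k: len(s) / n_samples for k, s in carriers.items()}


def _check_n_samples(table, n_samples):
    distinct = len({v.sample_id for v in table})
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_samples < distinct:
        raise ValueError(
            f"n_samples ({n_samples}) is smaller than the number of distinct "
            f"sample ids in the table ({distinct})"
        )


def filter_chip_wes(
    table: Sequence[AnnotatedVariant],
    panel: GenePanel,
    n_samples: int,
    thresholds: WesThresholds = WesThresholds(),
    samples: Optional[Sequence[str]] = None,
) -> tuple:
    """Full whole-exome CHIP cascade.

    Computes cohort frameshift frequencies, applies ``R1``--``R9`` to every
    variant, collapses 5-bp frameshift clusters per sample among survivors
    (dropped members are marked failed with rule ``C1``), then builds carrier
    profiles. ``samples`` defaults to the distinct sample ids seen in the
    table; pass the full cohort roster to include variant-free participants.

    Returns
    -------
    (decisions, profiles)
    """
    for v in table:
        v.validate()
    _check_n_samples(table, n_samples)
    fs_freq = cohort_frameshift_frequencies(table, n_samples)
    decisions = [
        evaluate_chip_rules(v, panel, fs_freq.get(v.allele_key, 0.0), thresholds)
        for v in table
    ]
    decisions = _apply_cluster_collapse(decisions)
    if samples is None:
        samples = sorted({v.sample_id for v in table})
    profiles = build_carrier_profiles(decisions, samples)
    return decisions, profiles


def _apply_cluster_collapse(decisions: Sequence[FilterDecision]) -> list:
    """Mark cluster-collapsed frameshift survivors' neighbours as failed (C1)."""
    passing_by_sample = defaultdict(list)
    for d in decisions:
        if d.verdict == "pass":
            passing_by_sample[d.variant.sample_id].append(d.variant)
    dropped = set()
    for sample_id, variants in passing_by_sample.items():
        kept = collapse_frameshift_clusters(variants)
        kept_ids = {id(v) for v in kept}
        for v in variants:
            if id(v) not in kept_ids:
                dropped.add((v.sample_id, v.chrom, v.pos, v.ref, v.alt))
    out = []
    for d in decisions:
        v = d.variant
        if d.verdict == "pass" and (v.sample_id, v.chrom, v.pos, v.ref, v.alt) in dropped:
            out.append(FilterDecision(v, d.failed_rules + (CLUSTER_RULE,)))
        else:
            out.append(d)
    return out


def filter_lymphoid_wes(
    table: Sequence[AnnotatedVariant],
    panel: GenePanel,
    n_samples: Optional[int] = None,
    thresholds: WesThresholds = WesThresholds(),
) -> list:
    """Lymphoid-driver cascade: ``R1``--``R9`` plus ``L1``/``L2``.

    ``n_samples`` (for the frameshift cohort-frequency denominator) defaults
    to the number of distinct sample ids in the table.
    """
    for v in table:
        v.validate()
    if n_samples is None:
        n_samples = max(1, len({v.sample_id for v in table}))
    _check_n_samples(table, n_samples)
    fs_freq = cohort_frameshift_frequencies(table, n_samples)
    return [
        evaluate_lymphoid_rules(v, panel, fs_freq.get(v.allele_key, 0.0), thresholds)
        for v in table
    ]


def filter_chip_panel(
    table: Sequence[AnnotatedVariant],
    panel: GenePanel,
    n_samples: int,
    thresholds: PanelThresholds = PanelThresholds(),
    samples: Optional[Sequence[str]] = None,
) -> tuple:
    """Targeted-panel cascade ``P1``--``P8`` plus carrier profiles."""
    for v in table:
        v.validate()
    _check_n_samples(table, n_samples)
    af = cohort_allele_frequencies(table, n_samples)
    decisions = [
        evaluate_panel_rules(v, panel, af.get(v.allele_key, 0.0), thresholds) for v in table
    ]
    if samples is None:
        samples = sorted({v.sample_id for v in table})
    profiles = build_carrier_profiles(decisions, samples)
    return decisions, profiles
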