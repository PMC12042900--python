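"""Seeded synthetic cohorts with known ground truth.

Generates the three input kinds the pipeline consumes — annotated variant
tables, per-locus array intensities, and phenotype/registry tables — from a
single :class:`SimConfig`, together with a :class:`TruthTable` recording
exactly what was planted (carrier status, true VAFs, and which filter rule
each decoy variant was built to violate).

Randomness comes from ``numpy.random.default_rng`` (PCG64); a fixed seed
gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variant_filtering import AnnotatedVariant, GenePanel
from .array_chip import HotspotLocus, IntensitySample

# Fabricated-but-stable coordinates for the simulated gene universe.
GENE_LOCI = {
    "DNMT3A": ("chr2", 25_234_000),
    "TET2": ("chr4", 105_233_000),
    "ASXL1": ("chr20", 32_358_000),
    "JAK2": ("chr9", 5_073_770),
    "SF3B1": ("chr2", 197_402_000),
    "SRSF2": ("chr17", 76_736_000),
    "TP53": ("chr17", 7_675_000),
    "PPM1D": ("chr17", 60_600_000),
    "KMT2D": ("chr12", 49_030_000),
    "KMT2A": ("chr11", 118_436_000),
    "ADGRV1": ("chr5", 90_529_000),
    "STAT3": ("chr17", 42_313_000),
}

CHIP_GENES = frozenset(
    {"DNMT3A", "TET2", "ASXL1", "JAK2", "SF3B1", "SRSF2", "TP53", "PPM1D"}
)
LYMPHOID_GENES = frozenset({"KMT2D", "KMT2A", "ADGRV1", "STAT3"})

DEFAULT_CHIP_PANEL = GenePanel(
    name="chip",
    genes=frozenset(CHIP_GENES),
    hotspot_exemptions=frozenset({("JAK2", "V617F"), ("DNMT3A", "882")}),
)
DEFAULT_LYMPHOID_PANEL = GenePanel(name="lymphoid", genes=LYMPHOID_GENES)

DEFAULT_LOCI = (
    HotspotLocus("JAK2_V617F", "JAK2", "V617F", "chr9", 5_073_770, "G", "T", 120, 200_000),
    HotspotLocus("DNMT3A_R882H", "DNMT3A", "R882H", "chr2", 25_234_373, "C", "T", 180, 200_000),
)

RA_SEROPOS_CODE = "M05"
RA_SERONEG_CODE = "M06"
HEM_MALIGNANCY_CODE = "C92"
DEFAULT_CODE_MAP = {
    "ra": [RA_SEROPOS_CODE, RA_SERONEG_CODE],
    "ra_seropositive": [RA_SEROPOS_CODE],
    "ra_seronegative": [RA_SERONEG_CODE],
    "hematologic_malignancy": [HEM_MALIGNANCY_CODE],
}


@dataclass
class SimConfig:
    """Knobs for the simulator; defaults target the cohort summary values
    the pipeline is designed around (≈3.8% overall CHIP prevalence rising
    to ≈7.8% at ages 60–69, OR ≈ 2.06 for prevalent RA given CHIP, HR ≈
    1.92 for death given CHIP in RA)."""

    n_participants: int = 10_000
    seed: int = 0
    # demographics
    age_min: float = 25.0
    age_max: float = 74.0
    male_fraction: float = 0.5
    smoking_prevalence: float = 0.45
    smoking_missing_fraction: float = 0.0
    n_pcs: int = 10
    # CHIP prevalence: logistic in age, calibrated to ~7.8% at age 65
    chip_intercept: float = -7.67
    chip_age_slope: float = 0.08
    gene_weights: dict = field(
        default_factory=lambda: {
            "DNMT3A": 0.42, "TET2": 0.36, "ASXL1": 0.08, "JAK2": 0.05,
            "SF3B1": 0.03, "SRSF2": 0.03, "TP53": 0.03,
        }
    )
    # true clone sizes: Beta, truncated
    vaf_alpha: float = 1.5
    vaf_beta: float = 12.0
    vaf_min: float = 0.02
    vaf_max: float = 0.45
    # sequencing depth
    coverage_wes: float = 48.0
    coverage_panel: float = 1700.0
    condition_reads_on_pass: bool = True
    # array intensity model
    theta_center: float = 0.03
    theta_sigma: float = 0.01
    strength_log_mu: float = 7.0
    strength_log_sigma: float = 0.25
    # phenotype effects
    or_ra_chip: float = 2.06
    ra_baseline_prevalence: float = 0.012
    seropositive_fraction: float = 0.8
    hem_malignancy_base: float = 0.004
    hem_or_chip: float = 5.0
    hr_death_chip_ra: float = 1.92
    death_baseline_hazard: float = 0.012  # per year
    followup_years: float = 16.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not self.gene_weights or any(w < 0 for w in self.gene_weights.values()):
            raise ValueError("gene_weights must be non-negative")
        if abs(sum(self.gene_weights.values()) - 1.0) > 1e-9:
            raise ValueError("gene_weights must sum to 1")
        for name in ("ra_baseline_prevalence", "hem_malignancy_base", "male_fraction",
                     "smoking_prevalence", "seropositive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.vaf_min < self.vaf_max <= 1.0:
            raise ValueError("require 0 <= vaf_min < vaf_max <= 1")
        if self.theta_sigma < 0 or self.coverage_wes <= 0 or self.coverage_panel <= 0:
            raise ValueError("noise/coverage parameters must be positive")


@dataclass
class TruthTable:
    """Ground truth for everything planted by the simulator."""

    participants: pd.DataFrame  # sample_id, chip, gene, protein_change, vaf, locus_id
    variants: Optional[pd.DataFrame] = None  # allele key, is_decoy, planted_rules, expected_pass
    array: Optional[pd.DataFrame] = None  # sample_id, locus_id, carrier, clone_fraction, vaf

    def clean_pass_keys(self) -> set:
        """(sample_id, chrom, pos, ref, alt) of variants planted to pass."""
        df = self.variants
        return set(
            map(tuple, df.loc[df["expected_pass"], ["sample_id", "chrom", "pos", "ref", "alt"]].to_numpy())
        )


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _truncated_beta(rng, a, b, lo, hi, size):
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.beta(a, b, size=need.size)
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def generate_cohort(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Simulate participants, registry events, and truth.

    Returns ``(participants, events, truth)`` where ``participants`` has one
    row per subject (covariates, dated sampling/death/censor columns, RA and
    malignancy status), ``events`` is the long-format registry table, and
    ``truth`` records the planted CHIP status, genes and VAFs.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    sample_ids = np.array([f"S{i:06d}" for i in range(n)])
    age = rng.uniform(config.age_min, config.age_max, n)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    smoking = rng.random(n) < config.smoking_prevalence
    smoking = smoking.astype(object)
    if config.smoking_missing_fraction > 0:
        smoking[rng.random(n) < config.smoking_missing_fraction] = None
    pcs = rng.standard_normal((n, config.n_pcs))

    chip = rng.random(n) < _logistic(config.chip_intercept + config.chip_age_slope * age)
    genes = np.array(list(config.gene_weights))
    weights = np.array([config.gene_weights[g] for g in genes])
    gene = np.where(chip, genes[rng.choice(len(genes), size=n, p=weights)], None)
    vaf = np.where(chip, _truncated_beta(rng, config.vaf_alpha, config.vaf_beta,
                                         config.vaf_min, config.vaf_max, n), np.nan)
    protein_change = np.empty(n, dtype=object)
    locus_id = np.empty(n, dtype=object)
    hotspot_draw = rng.random(n)
    for i in range(n):
        if not chip[i]:
            protein_change[i] = None
            locus_id[i] = None
        elif gene[i] == "JAK2":
            protein_change[i] = "V617F"
            locus_id[i] = "JAK2_V617F"
        elif gene[i] == "DNMT3A" and hotspot_draw[i] < 0.30:
            protein_change[i] = "R882H"
            locus_id[i] = "DNMT3A_R882H"
        else:
            protein_change[i] = f"A{100 + int(hotspot_draw[i] * 500)}T"
            locus_id[i] = None

    # prevalent RA depends on CHIP with the configured conditional OR
    ra_lp = _logit(config.ra_baseline_prevalence) + np.log(config.or_ra_chip) * chip
    ra = rng.random(n) < _logistic(ra_lp)
    seropositive = rng.random(n) < config.seropositive_fraction
    hem_lp = _logit(config.hem_malignancy_base) + np.log(config.hem_or_chip) * chip
    hem = rng.random(n) < _logistic(hem_lp)

    sampling_date = pd.Timestamp("2000-01-01") + pd.to_timedelta(
        rng.integers(0, 365, n), unit="D"
    )
    # overall survival from sampling: exponential, hazard multiplied for CHIP∧RA
    hazard = config.death_baseline_hazard * np.where(
        chip & ra, config.hr_death_chip_ra, 1.0
    )
    t_death = rng.exponential(1.0 / hazard)
    event = t_death < config.followup_years
    censor_date = sampling_date + pd.Timedelta(days=int(round(config.followup_years * 365.25)))
    death_days = np.round(np.minimum(t_death, config.followup_years) * 365.25).astype(int)
    death_date = pd.Series(
        np.where(event, sampling_date + pd.to_timedelta(death_days, unit="D"), pd.NaT)
    )

    participants = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "sex": sex,
            "smoking_ever": smoking,
            "sampling_date": sampling_date,
            "death_date": pd.to_datetime(death_date),
            "censor_date": censor_date,
            "ra_prevalent": ra,
            "ra_serotype": np.where(ra, np.where(seropositive, "seropositive", "seronegative"), "none"),
            "hem_malignancy": hem,
        }
    )
    for j in range(config.n_pcs):
        participants[f"pc{j + 1}"] = pcs[:, j]

    events = _build_events(participants, rng)
    truth = TruthTable(
        participants=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "chip": chip,
                "gene": gene,
                "protein_change": protein_change,
                "vaf": vaf,
                "locus_id": locus_id,
            }
        )
    )
    return participants, events, truth


def _logit(p):
    return math.log(p / (1.0 - p))


def _build_events(participants: pd.DataFrame, rng) -> pd.DataFrame:
    """Registry events consistent with the participant table's dates."""
    rows = []
    for row in participants.itertuples(index=False):
        if row.ra_prevalent:
            code = RA_SEROPOS_CODE if row.ra_serotype == "seropositive" else RA_SERONEG_CODE
            offset = int(rng.integers(30, 3650))
            rows.append((row.sample_id, code, row.sampling_date - pd.Timedelta(days=offset)))
            # seropositive-dominance exercise: some seropositives also carry a
            # seronegative code earlier in the record
            if row.ra_serotype == "seropositive" and rng.random() < 0.1:
                rows.append(
                    (row.sample_id, RA_SERONEG_CODE,
                     row.sampling_date - pd.Timedelta(days=offset + 200))
                )
        if row.hem_malignancy:
            offset = int(rng.integers(-1500, 1500))
            date = row.sampling_date + pd.Timedelta(days=offset)
            end = row.death_date if pd.notna(row.death_date) else row.censor_date
            if date > end:
                date = end
            rows.append((row.sample_id, HEM_MALIGNANCY_CODE, date))
    return pd.DataFrame(rows, columns=["sample_id", "code", "date"])


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def _sample_reads(rng, coverage, vaf, condition_on_pass, min_depth, min_alt):
    """Draw (depth, alt, ref_fwd, ref_rev, alt_fwd, alt_rev).

    When ``condition_on_pass`` the draw is rejected until the read-level
    rules (depth, alt reads, both strands for both alleles) hold, so planted
    clean variants are guaranteed to pass; a deterministic fallback kicks in
    after 1000 rejections.
    """
    for _ in range(1000):
        depth = int(rng.poisson(coverage))
        alt = int(rng.binomial(depth, vaf)) if depth > 0 else 0
        ref = depth - alt
        alt_fwd = int(rng.binomial(alt, 0.5)) if alt > 0 else 0
        ref_fwd = int(rng.binomial(ref, 0.5)) if ref > 0 else 0
        reads = (depth, alt, ref_fwd, ref - ref_fwd, alt_fwd, alt - alt_fwd)
        if not condition_on_pass:
            return reads
        if (
            depth >= min_depth
            and alt >= min_alt
            and min(alt_fwd, alt - alt_fwd) >= 1
            and min(ref_fwd, ref - ref_fwd) >= 1
        ):
            return reads
    depth = max(int(coverage), min_depth, 4)
    alt = max(min_alt, int(round(depth * vaf)), 2)
    alt = min(alt, depth - 2)
    ref = depth - alt
    return (depth, alt, ref // 2, ref - ref // 2, alt // 2, alt - alt // 2)


def _clean_variant(rng, sample_id, gene, protein_change, vaf, config, mode, consequence="missense"):
    chrom, base = GENE_LOCI.get(gene, ("chr1", 1_000_000))
    pos = base + int(rng.integers(0, 200_000))
    coverage = config.coverage_wes if mode == "wes" else config.coverage_panel
    min_depth = 10 if mode == "wes" else 100
    depth, alt, rf, rr, af, ar = _sample_reads(
        rng, coverage, vaf, config.condition_reads_on_pass, min_depth, 2
    )
    ref = "ACGT"[int(rng.integers(0, 4))]
    alt_allele = rng.choice([b for b in "ACGT" if b != ref])
    return AnnotatedVariant(
        sample_id=sample_id, chrom=chrom, pos=pos,
        ref=ref, alt=str(alt_allele),
        gene=gene, consequence=consequence,
        splice_distance_bp=1 if consequence == "splice" else None,
        caller_label="PASS", somatic_quality=float(rng.uniform(10, 60)),
        germline_quality=float(rng.uniform(0, 5)),
        total_depth=depth, alt_depth=alt,
        ref_fwd=rf, ref_rev=rr, alt_fwd=af, alt_rev=ar,
        gnomad_max_pop_af=0.0, cosmic_count=int(rng.integers(3, 50)),
        reported_lchip=False, reported_all=False, protein_change=protein_change,
    )


def generate_variant_table(
    participants: pd.DataFrame,
    truth: TruthTable,
    config: SimConfig,
    mode: str = "wes",
    include_decoys: bool = True,
    rng: Optional[np.random.Generator] = None,
):
    """Emit an annotated variant table for the cohort's true carriers.

    Read evidence is Poisson depth + binomial allele sampling with a 50/50
    strand split. With ``include_decoys`` one variant is additionally
    planted per filter rule, violating exactly the rule(s) recorded for it
    in the returned truth (``truth.variants`` is filled in place).

    Note: the WES frameshift cohort-frequency rule means frameshift decoys
    are only single-rule violations when the cohort has >= 2000 samples; the
    panel cohort-frequency decoy likewise needs >= 100 samples.
    """
    if mode not in ("wes", "panel"):
        raise ValueError("mode must be 'wes' or 'panel'")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    variants, truth_rows = [], []
    carriers = truth.participants[truth.participants["chip"]]
    for row in carriers.itertuples(index=False):
        if row.gene not in GENE_LOCI:
            continue
        v = _clean_variant(rng, row.sample_id, row.gene, row.protein_change, row.vaf, config, mode)
        variants.append(v)
        # panel mode applies a VAF window; clean variants whose realized VAF
        # falls outside it are recorded as planted rule violations
        rules = ()
        if mode == "panel":
            if v.vaf > 0.40:
                rules = ("P6",)
            elif v.vaf < 0.02:
                rules = ("P8",)
        truth_rows.append(_truth_row(v, False, rules, not rules, row.vaf))
    if include_decoys:
        decoys = _plant_decoys(rng, participants, config, mode)
        for v, rules in decoys:
            variants.append(v)
            truth_rows.append(_truth_row(v, True, rules, len(rules) == 0, v.vaf))
    truth.variants = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "gene",
                 "is_decoy", "planted_rules", "expected_pass", "true_vaf"],
    )
    return variants


def _truth_row(v: AnnotatedVariant, is_decoy, rules, expected_pass, true_vaf):
    return (v.sample_id, v.chrom, v.pos, v.ref, v.alt, v.gene,
            is_decoy, ";".join(rules), expected_pass, true_vaf)


def _passing_template(rng, sample_id, config, mode, gene="TET2", **overrides):
    vaf = overrides.pop("vaf", 0.10)
    consequence = overrides.pop("consequence", "missense")
    v = _clean_variant(rng, sample_id, gene, None, vaf, config, mode, consequence)
    if overrides:
        from dataclasses import replace
        v = replace(v, **overrides)
    return v


def _plant_decoys(rng, participants, config, mode):
    """One decoy per rule, each violating exactly the rules it is named for."""
    ids = participants["sample_id"].to_numpy()
    pick = lambda: ids[int(rng.integers(0, len(ids)))]
    out = []
    if mode == "wes":
        n = len(ids)
        out.append((_passing_template(rng, pick(), config, mode, gene="GENE_OFF_PANEL"), ("R1",)))
        out.append((_passing_template(rng, pick(), config, mode, gnomad_max_pop_af=0.002), ("R2",)))
        out.append((_passing_template(rng, pick(), config, mode, caller_label="LowQual"), ("R3",)))
        out.append((_passing_template(rng, pick(), config, mode, somatic_quality=2.0), ("R4",)))
        out.append((_passing_template(rng, pick(), config, mode, germline_quality=15.0), ("R5",)))
        out.append(
            (_passing_template(rng, pick(), config, mode, total_depth=9, alt_depth=2,
                               ref_fwd=3, ref_rev=4, alt_fwd=1, alt_rev=1), ("R6",))
        )
        v = _passing_template(rng, pick(), config, mode)
        alt = v.alt_depth
        from dataclasses import replace
        out.append((replace(v, alt_fwd=alt, alt_rev=0), ("R7",)))
        out.append(
            (_passing_template(rng, pick(), config, mode, consequence="splice",
                               splice_distance_bp=3), ("R8",))
        )
        # recurrent frameshift: plant the same allele in > 0.05% of samples
        n_recurrent = int(math.floor(n * 0.0005)) + 1
        chrom, base = GENE_LOCI["ASXL1"]
        fs_pos = base + 9000
        fs_samples = rng.choice(ids, size=min(n_recurrent, len(ids)), replace=False)
        for sid in fs_samples:
            out.append(
                (_passing_template(rng, sid, config, mode, gene="ASXL1",
                                   consequence="frameshift", chrom=chrom, pos=fs_pos,
                                   ref="AT", alt="A"), ("R9",))
            )
        # 5-bp frameshift cluster in one sample: lower-VAF member collapses (C1)
        sid = pick()
        chrom, base = GENE_LOCI["TET2"]
        keeper = _passing_template(rng, sid, config, mode, gene="TET2",
                                   consequence="frameshift", chrom=chrom,
                                   pos=base + 7000, ref="GC", alt="G", vaf=0.20)
        loser = _passing_template(rng, sid, config, mode, gene="TET2",
                                  consequence="frameshift", chrom=chrom,
                                  pos=base + 7003, ref="TA", alt="T", vaf=0.05)
        out.append((keeper, ()))  # keeper survives the collapse: expected to pass
        out.append((loser, ("C1",)))
    else:
        n = len(ids)
        out.append((_passing_template(rng, pick(), config, mode, caller_label="LowQual"), ("P1",)))
        out.append((_passing_template(rng, pick(), config, mode, gnomad_max_pop_af=0.002), ("P2",)))
        # common artifact allele in > 1% of samples
        n_common = int(math.floor(n * 0.01)) + 1
        chrom, base = GENE_LOCI["TP53"]
        common_pos = base + 8000
        for sid in rng.choice(ids, size=min(n_common, len(ids)), replace=False):
            out.append(
                (_passing_template(rng, sid, config, mode, gene="TP53", chrom=chrom,
                                   pos=common_pos, ref="C", alt="G"), ("P3",))
            )
        out.append(
            (_passing_template(rng, pick(), config, mode, total_depth=99, alt_depth=10,
                               ref_fwd=44, ref_rev=45, alt_fwd=5, alt_rev=5), ("P4",))
        )
        out.append(
            (_passing_template(rng, pick(), config, mode, total_depth=150, alt_depth=1,
                               ref_fwd=74, ref_rev=75, alt_fwd=1, alt_rev=0), ("P5", "P7"))
        )
        out.append(
            (_passing_template(rng, pick(), config, mode, total_depth=1000, alt_depth=410,
                               ref_fwd=295, ref_rev=295, alt_fwd=205, alt_rev=205), ("P6",))
        )
        v = _passing_template(rng, pick(), config, mode)
        from dataclasses import replace
        out.append((replace(v, alt_fwd=v.alt_depth, alt_rev=0), ("P7",)))
        out.append(
            (_passing_template(rng, pick(), config, mode, total_depth=1000, alt_depth=19,
                               ref_fwd=490, ref_rev=491, alt_fwd=10, alt_rev=9), ("P8",))
        )
    return out


# ---------------------------------------------------------------------------
# Array intensities
# ---------------------------------------------------------------------------

def generate_array_intensities(
    participants: pd.DataFrame,
    truth: TruthTable,
    config: SimConfig,
    loci: Sequence[HotspotLocus] = DEFAULT_LOCI,
    rng: Optional[np.random.Generator] = None,
):
    """Two-channel intensities per participant per hotspot locus.

    Non-carriers draw theta ~ N(center, sigma); a carrier with clone
    fraction ``c`` (heterozygous somatic variant, so VAF = c/2) draws
    theta ~ N(center + VAF, sigma). Channel strength is log-normal;
    ``x = s * (1 - theta)``, ``y = s * theta``. Fills ``truth.array``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    tp = truth.participants.set_index("sample_id")
    records, truth_rows = [], []
    for locus in loci:
        for sid in participants["sample_id"]:
            row = tp.loc[sid]
            is_carrier = bool(row["chip"]) and row["locus_id"] == locus.locus_id
            vaf = float(row["vaf"]) if is_carrier else 0.0
            theta = rng.normal(config.theta_center + vaf, config.theta_sigma)
            theta = min(max(theta, 0.0), 1.0)
            strength = float(rng.lognormal(config.strength_log_mu, config.strength_log_sigma))
            records.append(
                IntensitySample(sid, locus.locus_id, strength * (1 - theta), strength * theta)
            )
            truth_rows.append((sid, locus.locus_id, is_carrier, 2 * vaf, vaf))
    truth.array = pd.DataFrame(
        truth_rows, columns=["sample_id", "locus_id", "carrier", "clone_fraction", "vaf"]
    )
    return records


def simulate_locus_thetas(
    n_ref: int,
    carrier_vafs: Sequence[float],
    center: float = 0.03,
    sigma: float = 0.01,
    rng: Optional[np.random.Generator] = None,
    locus_id: str = "L1",
):
    """Small-scale per-locus generator for caller property tests.

    Returns ``(records, truth)`` where the first ``len(carrier_vafs)``
    samples are carriers displaced by their VAF.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    vafs = np.concatenate([np.asarray(carrier_vafs, dtype=float), np.zeros(n_ref)])
    thetas = np.clip(rng.normal(center + vafs, sigma), 0.0, 1.0)
    strength = rng.lognormal(7.0, 0.25, size=vafs.size)
    records = [
        IntensitySample(f"A{i:06d}", locus_id, float(s * (1 - t)), float(s * t))
        for i, (t, s) in enumerate(zip(thetas, strength))
    ]
    truth = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "locus_id": locus_id,
            "carrier": vafs > 0,
            "vaf": vafs,
        }
    )
    return records, truth


# ---------------------------------------------------------------------------
# Focused cohorts for parameter-recovery experiments
# ---------------------------------------------------------------------------

def generate_logistic_cohort(
    n: int,
    exposure_prevalence: float,
    outcome_baseline: float,
    odds_ratio: float,
    rng: np.random.Generator,
    n_pcs: int = 10,
) -> pd.DataFrame:
    """Exposure/outcome cohort with a known conditional OR and null covariates."""
    exposure = (rng.random(n) < exposure_prevalence).astype(int)
    lp = _logit(outcome_baseline) + np.log(odds_ratio) * exposure
    outcome = (rng.random(n) < _logistic(lp)).astype(int)
    df = pd.DataFrame(
        {
            "sample_id": [f"L{i:06d}" for i in range(n)],
            "exposure": exposure,
            "outcome": outcome,
            "age": rng.uniform(25, 74, n),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "smoking_ever": rng.random(n) < 0.45,
        }
    )
    for j in range(n_pcs):
        df[f"pc{j + 1}"] = rng.standard_normal(n)
    return df


def generate_survival_cohort(
    n: int,
    exposure_prevalence: float,
    hazard_ratio: float,
    rng: np.random.Generator,
    baseline_hazard: float = 0.025,
    followup_years: float = 15.0,
) -> pd.DataFrame:
    """Exponential survival cohort with a known exposure HR."""
    exposure = (rng.random(n) < exposure_prevalence).astype(int)
    hazard = baseline_hazard * hazard_ratio ** exposure
    t = rng.exponential(1.0 / hazard)
    duration = np.minimum(t, followup_years)
    event = (t < followup_years).astype(int)
    return pd.DataFrame(
        {
            "sample_id": [f"V{i:06d}" for i in range(n)],
            "exposure": exposure,
            "duration_years": duration,
            "event": event,
            "age": rng.uniform(40, 80, n),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        }
    )
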