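"""SNP-array hotspot CHIP detection from two-channel probe intensities.

Per locus: normalize raw intensities to a B-allele proportion (theta), fit
the homozygous-reference cluster robustly (median / scaled MAD with one
trimming pass), call carriers as high-z outliers with a minimum relative-BAF
displacement, qualify loci against cohort prevalence and phenotype
heuristics, and quantify concordance with sequencing-derived VAFs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class HotspotLocus:
    """An array probe over a recurrent somatic hotspot.

    ``reference_count`` / ``reference_n`` give the carrier count and cohort
    size at this locus in the external sequencing reference used for
    prevalence-ratio screening.
    """

    locus_id: str
    gene: str
    protein_change: str
    chrom: str
    pos: int
    ref: str
    alt: str
    reference_count: int
    reference_n: int

    def __post_init__(self):
        if self.reference_n <= self.reference_count:
            raise ValueError("reference_n must exceed reference_count")
        if self.reference_count < 0:
            raise ValueError("reference_count must be >= 0")


@dataclass(frozen=True)
class IntensitySample:
    """Per-sample raw two-channel signal at one locus."""

    sample_id: str
    locus_id: str
    x_raw: float
    y_raw: float

    @property
    def theta(self) -> float:
        """B-allele proportion; NaN when both channels are zero."""
        total = self.x_raw + self.y_raw
        if total <= 0:
            return float("nan")
        return self.y_raw / total


@dataclass(frozen=True)
class ClusterFit:
    center: float
    scale: float
    n_used: int
    n_zero_excluded: int
    n_trimmed: int


@dataclass(frozen=True)
class ArrayCarrierCall:
    sample_id: str
    locus_id: str
    carrier: bool
    relative_baf: float
    robust_z: float


@dataclass(frozen=True)
class LocusQualification:
    locus_id: str
    n_samples: int
    n_carriers: int
    cohort_prevalence: float
    prevalence_ratio: float
    age_beta: float
    age_p: float
    hem_beta: float
    hem_p: float
    high_confidence: bool
    reasons: tuple


def thetas_from_records(records: Iterable[IntensitySample]) -> np.ndarray:
    return np.array([r.theta for r in records], dtype=float)


def fit_reference_cluster(
    records,
    min_samples: int = 50,
    scale_floor: float = 0.002,
    trim_k: float = 4.0,
) -> ClusterFit:
    """Fit the homozygous-reference cluster of a somatic hotspot locus.

    ``records`` may be a sequence of :class:`IntensitySample` or an array of
    theta values. Zero-intensity samples (theta NaN) are excluded and
    counted. Center = median, scale = 1.4826 x MAD floored at
    ``scale_floor``; one trimming pass removes points with
    ``|theta - center| / scale > trim_k`` before refitting.
    """
    if len(records) and isinstance(records[0], IntensitySample):
        thetas = thetas_from_records(records)
    else:
        thetas = np.asarray(records, dtype=float)
    mask = np.isfinite(thetas)
    n_zero = int((~mask).sum())
    thetas = thetas[mask]
    if thetas.size < min_samples:
        raise ValueError(
            f"need at least {min_samples} usable samples to fit a reference "
            f"cluster, got {thetas.size}"
        )
    center = float(np.median(thetas))
    scale = max(MAD_TO_SIGMA * float(np.median(np.abs(thetas - center))), scale_floor)
    keep = np.abs(thetas - center) / scale <= trim_k
    n_trimmed = int((~keep).sum())
    trimmed = thetas[keep]
    center = float(np.median(trimmed))
    scale = max(MAD_TO_SIGMA * float(np.median(np.abs(trimmed - center))), scale_floor)
    return ClusterFit(center, scale, int(trimmed.size), n_zero, n_trimmed)


def call_hotspot_carriers(
    records: Sequence[IntensitySample],
    cluster: ClusterFit,
    z_min: float = 5.0,
    baf_floor: float = 0.05,
    het_center: Optional[float] = None,
) -> list:
    """Call carriers as robust-z outliers above the reference cluster.

    ``relative_baf`` is theta offset so the reference cluster center maps to
    0, clamped to [0, 1]. When a heterozygous-germline reference center is
    supplied (``het_center``, the theta where BAF = 0.5 sits), the offset is
    rescaled so that span maps to 0.5; otherwise the raw offset is used.
    Carrier iff ``robust_z >= z_min`` and ``relative_baf >= baf_floor``.
    Zero-intensity samples yield non-carrier calls with NaN fields.
    """
    if z_min <= 0 or baf_floor <= 0:
        raise ValueError("z_min and baf_floor must be positive")
    calls = []
    for r in records:
        theta = r.theta
        if math.isnan(theta):
            calls.append(ArrayCarrierCall(r.sample_id, r.locus_id, False, float("nan"), float("nan")))
            continue
        z = (theta - cluster.center) / cluster.scale
        baf = min(max(theta - cluster.center, 0.0), 1.0)
        if het_center is not None and het_center > cluster.center:
            baf = min(max(0.5 * baf / (het_center - cluster.center), 0.0), 1.0)
        carrier = z >= z_min and baf >= baf_floor
        calls.append(ArrayCarrierCall(r.sample_id, r.locus_id, carrier, baf, z))
    return calls


def qualification_rule(
    prevalence_ratio: float,
    age_beta: float,
    age_p: float,
    hem_beta: float,
    hem_p: float,
    max_ratio: float = 10.0,
    lenient_ratio: float = 2.0,
    age_p_max: float = 0.1,
    hem_p_max: float = 0.05,
) -> tuple:
    """High-confidence decision for one locus.

    Qualify iff prevalence_ratio < ``max_ratio`` and either both the age and
    hematologic-malignancy associations are positive and significant at
    their cutoffs, or the ratio is < ``lenient_ratio`` and at least one of
    the two associations holds. Returns ``(high_confidence, reasons)``.
    """
    reasons = []
    age_ok = np.isfinite(age_beta) and age_beta > 0 and age_p < age_p_max
    hem_ok = np.isfinite(hem_beta) and hem_beta > 0 and hem_p < hem_p_max
    if not np.isfinite(prevalence_ratio):
        return False, ("prevalence_ratio_undefined",)
    if prevalence_ratio >= max_ratio:
        reasons.append(f"prevalence_ratio>={max_ratio:g}")
        return False, tuple(reasons)
    if age_ok and hem_ok:
        return True, ()
    if prevalence_ratio < lenient_ratio and (age_ok or hem_ok):
        return True, ()
    if not age_ok:
        reasons.append("no_positive_age_association")
    if not hem_ok:
        reasons.append("no_positive_hematologic_association")
    return False, tuple(reasons)


def _univariate_logit(y: np.ndarray, x: np.ndarray) -> tuple:
    """(beta, two-sided p) for y ~ intercept + x; NaN on failure."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(np.asarray(y, dtype=float), X).fit(disp=0, maxiter=200)
        if not np.isfinite(res.params[1]) or not np.isfinite(res.bse[1]):
            return float("nan"), float("nan")
        return float(res.params[1]), float(res.pvalues[1])
    except Exception:
        return float("nan"), float("nan")


def qualify_locus(
    locus: HotspotLocus,
    calls: Sequence[ArrayCarrierCall],
    phenotypes: pd.DataFrame,
    **rule_kwargs,
) -> LocusQualification:
    """Screen one locus with the prevalence/age/malignancy heuristic.

    ``phenotypes`` needs columns ``sample_id``, ``age`` and
    ``hem_malignancy`` (any-time diagnosis flag). Loci with zero carriers
    are flagged unqualifiable, not errored.
    """
    df = pd.DataFrame(
        {"sample_id": [c.sample_id for c in calls], "carrier": [c.carrier for c in calls]}
    )
    merged = df.merge(phenotypes[["sample_id", "age", "hem_malignancy"]], on="sample_id")
    n = len(merged)
    n_carriers = int(merged["carrier"].sum())
    if n == 0:
        raise ValueError(f"no calls joinable to phenotypes for locus {locus.locus_id}")
    prevalence = n_carriers / n
    ref_prev = locus.reference_count / locus.reference_n
    ratio = prevalence / ref_prev if ref_prev > 0 else float("inf")
    if n_carriers == 0:
        return LocusQualification(
            locus.locus_id, n, 0, 0.0, 0.0, float("nan"), float("nan"),
            float("nan"), float("nan"), False, ("no_carriers",),
        )
    y = merged["carrier"].to_numpy(dtype=float)
    age_beta, age_p = _univariate_logit(y, merged["age"].to_numpy())
    hem_beta, hem_p = _univariate_logit(y, merged["hem_malignancy"].to_numpy(dtype=float))
    high_conf, reasons = qualification_rule(ratio, age_beta, age_p, hem_beta, hem_p, **rule_kwargs)
    return LocusQualification(
        locus.locus_id, n, n_carriers, prevalence, ratio,
        age_beta, age_p, hem_beta, hem_p, high_conf, reasons,
    )


@dataclass(frozen=True)
class ConcordanceReport:
    sensitivity_by_bin: dict
    n_truth: int
    n_detected: int
    slope: float
    intercept: float
    slope_p: float
    flags: tuple = ()


def concordance_analysis(
    calls: Sequence[ArrayCarrierCall],
    truth: Sequence[tuple],
    bin_edges: Sequence[float] = (0.10,),
) -> ConcordanceReport:
    """Sensitivity by VAF bin plus BAF-vs-VAF regression among true carriers.

    ``truth`` is an iterable of ``(sample_id, locus_id, vaf)`` for
    sequencing-confirmed carriers. Sensitivity is computed per VAF bin with
    edges ``bin_edges`` (default: below / at-or-above 10%). The regression
    is ordinary least squares of ``relative_baf`` on ``vaf`` over all truth
    carriers with a usable call, with a Wald two-sided p for the slope.
    """
    call_map = {(c.sample_id, c.locus_id): c for c in calls}
    edges = [0.0] + sorted(bin_edges) + [float("inf")]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"[{lo:g},{hi:g})" if math.isfinite(hi) else f">={lo:g}")
    counts = {lab: [0, 0] for lab in labels}  # detected, total
    bafs, vafs = [], []
    flags = []
    for sample_id, locus_id, vaf in truth:
        if not 0.0 <= vaf <= 1.0:
            raise ValueError(f"truth VAF out of [0,1]: {vaf}")
        idx = np.searchsorted(edges, vaf, side="right") - 1
        lab = labels[min(idx, len(labels) - 1)]
        counts[lab][1] += 1
        call = call_map.get((sample_id, locus_id))
        if call is not None and call.carrier:
            counts[lab][0] += 1
        if call is not None and np.isfinite(call.relative_baf):
            bafs.append(call.relative_baf)
            vafs.append(vaf)
    if not any(t for _, t in counts.values()):
        flags.append("empty_truth_set")
    sensitivity = {
        lab: (det / tot if tot else float("nan")) for lab, (det, tot) in counts.items()
    }
    slope = intercept = slope_p = float("nan")
    if len(vafs) >= 3 and len(set(vafs)) > 1:
        X = sm.add_constant(np.array(vafs))
        res = sm.OLS(np.array(bafs), X).fit()
        intercept, slope = (float(res.params[0]), float(res.params[1]))
        slope_p = float(res.pvalues[1])
    else:
        flags.append("regression_undefined")
    return ConcordanceReport(
        sensitivity, sum(t for _, t in counts.values()),
        sum(d for d, _ in counts.values()), slope, intercept, slope_p, tuple(flags),
    )
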