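"""Readers and writers for the plain-text interchange formats.

The canonical dialect is TSV with one annotated variant per row (columns
below); VCF v4.2 is supported as an alternative input path with a field map
naming the INFO/FORMAT keys that carry the caller scores and strand counts.
Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variant_filtering import (
    AnnotatedVariant,
    CarrierProfile,
    FilterDecision,
    GenePanel,
)
from .array_chip import ArrayCarrierCall, HotspotLocus, IntensitySample, LocusQualification

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
    "caller_label", "somatic_quality", "germline_quality",
    "total_depth", "alt_depth", "ref_fwd", "ref_rev", "alt_fwd", "alt_rev",
    "gnomad_max_pop_af", "cosmic_count", "reported_lchip", "reported_all",
    "splice_distance_bp", "protein_change",
]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "True": True, "False": False}

DEFAULT_VCF_FIELD_MAP = {
    "gene": "GENE",
    "consequence": "CSQ",
    "somatic_quality": "SQ",
    "germline_quality": "GQ",
    "gnomad_max_pop_af": "GNOMAD_AF",
    "cosmic_count": "COSMIC_CNT",
    "splice_distance_bp": "SPLICE_DIST",
    "protein_change": "PCHANGE",
    "strand_counts": "SB",  # FORMAT: ref_fwd,ref_rev,alt_fwd,alt_rev
}


def _opt_int(value):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(float(value))


def _opt_str(value):
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    return str(value)


def read_variants_tsv(path) -> list:
    """Read the documented variant TSV dialect.

    Rows that fail type coercion are rejected with a diagnostic carrying the
    1-based data line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV {path} is missing columns: {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                AnnotatedVariant(
                    sample_id=row.sample_id,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene,
                    consequence=row.consequence,
                    caller_label=row.caller_label,
                    somatic_quality=float(row.somatic_quality),
                    germline_quality=float(row.germline_quality),
                    total_depth=_opt_int(row.total_depth),
                    alt_depth=_opt_int(row.alt_depth),
                    ref_fwd=_opt_int(row.ref_fwd),
                    ref_rev=_opt_int(row.ref_rev),
                    alt_fwd=_opt_int(row.alt_fwd),
                    alt_rev=_opt_int(row.alt_rev),
                    gnomad_max_pop_af=float(row.gnomad_max_pop_af),
                    cosmic_count=int(float(row.cosmic_count)),
                    reported_lchip=_BOOL_MAP[row.reported_lchip],
                    reported_all=_BOOL_MAP[row.reported_all],
                    splice_distance_bp=_opt_int(row.splice_distance_bp),
                    protein_change=_opt_str(row.protein_change),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed variant row at data line {i}: {exc}") from exc
    return out


def write_variants_tsv(variants: Iterable[AnnotatedVariant], path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                **{c: getattr(v, c) for c in VARIANT_COLUMNS if c != "splice_distance_bp"},
                "splice_distance_bp": "" if v.splice_distance_bp is None else v.splice_distance_bp,
                "protein_change": "" if v.protein_change is None else v.protein_change,
            }
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_vcf(path, field_map: Optional[Mapping[str, str]] = None) -> list:
    """Read annotated variants from a VCF v4.2 file.

    Multi-allelic records are decomposed to one biallelic row per alt.
    FORMAT ``AD`` supplies (ref, alt) depths and ``DP`` the total depth; the
    remaining annotations come from the INFO/FORMAT keys in ``field_map``
    (defaults in :data:`DEFAULT_VCF_FIELD_MAP`). A missing mapped field is a
    hard error naming it.
    """
    import pysam

    fm = dict(DEFAULT_VCF_FIELD_MAP)
    if field_map:
        fm.update(field_map)
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            info = rec.info
            for sample_name in sample_names:
                fmt = rec.samples[sample_name]
                ad = fmt.get("AD")
                dp = fmt.get("DP")
                if ad is None:
                    raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks FORMAT/AD")
                sb = fmt.get(fm["strand_counts"])
                for alt_index, alt in enumerate(rec.alts or (), start=1):
                    alt_depth = int(ad[alt_index])
                    total = int(dp) if dp is not None else int(sum(x for x in ad if x is not None))
                    strand = None
                    if sb is not None:
                        strand = [int(x) for x in sb]
                    def _info(key_name, default=None, required=False):
                        key = fm[key_name]
                        if key in info:
                            val = info[key]
                            if isinstance(val, tuple):
                                val = val[min(alt_index - 1, len(val) - 1)]
                            return val
                        if required:
                            raise ValueError(
                                f"{path}: record {rec.chrom}:{rec.pos} lacks INFO/{key} "
                                f"(mapped field {key_name!r})"
                            )
                        return default
                    out.append(
                        AnnotatedVariant(
                            sample_id=sample_name,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            gene=str(_info("gene", required=True)),
                            consequence=str(_info("consequence", required=True)),
                            caller_label=";".join(rec.filter.keys()) or "PASS",
                            somatic_quality=float(_info("somatic_quality", required=True)),
                            germline_quality=float(_info("germline_quality", required=True)),
                            total_depth=total,
                            alt_depth=alt_depth,
                            ref_fwd=strand[0] if strand else None,
                            ref_rev=strand[1] if strand else None,
                            alt_fwd=strand[2] if strand else None,
                            alt_rev=strand[3] if strand else None,
                            gnomad_max_pop_af=float(_info("gnomad_max_pop_af", 0.0)),
                            cosmic_count=int(_info("cosmic_count", 0)),
                            splice_distance_bp=_opt_int(_info("splice_distance_bp")),
                            protein_change=_opt_str(_info("protein_change")),
                        )
                    )
    return out


def read_variants(path, dialect: str = "tsv", field_map=None) -> list:
    if dialect == "tsv":
        return read_variants_tsv(path)
    if dialect == "vcf":
        return read_variants_vcf(path, field_map)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Panels, decisions, profiles
# ---------------------------------------------------------------------------

def read_gene_panel(path, name: Optional[str] = None) -> GenePanel:
    """Two-column TSV: gene, optional exemption (protein change or codon)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene" not in df.columns:
        raise ValueError(f"panel file {path} must have a 'gene' column")
    genes = frozenset(df["gene"])
    exemptions = set()
    if "exemption" in df.columns:
        for _, row in df.iterrows():
            if row["exemption"]:
                exemptions.add((row["gene"], row["exemption"]))
    return GenePanel(name or Path(path).stem, genes, frozenset(exemptions))


def write_gene_panel(panel: GenePanel, path) -> None:
    ex = {g: c for g, c in panel.hotspot_exemptions}
    pd.DataFrame(
        {"gene": sorted(panel.genes), "exemption": [ex.get(g, "") for g in sorted(panel.genes)]}
    ).to_csv(path, sep="\t", index=False)


def write_decisions_tsv(decisions: Iterable[FilterDecision], path) -> None:
    rows = [
        {
            "sample_id": d.variant.sample_id,
            "chrom": d.variant.chrom,
            "pos": d.variant.pos,
            "ref": d.variant.ref,
            "alt": d.variant.alt,
            "gene": d.variant.gene,
            "vaf": f"{d.variant.vaf:.6g}",
            "verdict": d.verdict,
            "failed_rules": ";".join(d.failed_rules),
        }
        for d in decisions
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "verdict", "failed_rules"],
    ).to_csv(path, sep="\t", index=False)


def write_profiles_tsv(profiles: Iterable[CarrierProfile], path) -> None:
    rows = [
        {
            "sample_id": p.sample_id,
            "carrier": p.carrier,
            "n_variants": p.n_variants,
            "max_vaf": "" if p.max_vaf is None else f"{p.max_vaf:.6g}",
            "vaf_stratum": p.vaf_stratum or "",
            **{f"group_{k}": v for k, v in p.gene_groups.items()},
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Array intensities and loci
# ---------------------------------------------------------------------------

def read_intensities_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    needed = ["sample_id", "locus_id", "x_raw", "y_raw"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"intensity TSV {path} is missing columns: {missing}")
    return [
        IntensitySample(r.sample_id, r.locus_id, float(r.x_raw), float(r.y_raw))
        for r in df.itertuples(index=False)
    ]


def write_intensities_tsv(records: Iterable[IntensitySample], path) -> None:
    pd.DataFrame(
        [
            {"sample_id": r.sample_id, "locus_id": r.locus_id,
             "x_raw": f"{r.x_raw:.6f}", "y_raw": f"{r.y_raw:.6f}"}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chrom": str})
    return [
        HotspotLocus(
            r.locus_id, r.gene, r.protein_change, r.chrom, int(r.pos), r.ref, r.alt,
            int(r.reference_count), int(r.reference_n),
        )
        for r in df.itertuples(index=False)
    ]


def write_loci_tsv(loci: Iterable[HotspotLocus], path) -> None:
    pd.DataFrame([l.__dict__ for l in loci]).to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls: Iterable[ArrayCarrierCall], path) -> None:
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    return [
        ArrayCarrierCall(r.sample_id, r.locus_id, bool(r.carrier),
                         float(r.relative_baf), float(r.robust_z))
        for r in df.itertuples(index=False)
    ]


def write_qualifications_tsv(quals: Iterable[LocusQualification], path) -> None:
    rows = []
    for q in quals:
        d = dict(q.__dict__)
        d["reasons"] = ";".join(d["reasons"])
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotypes / events
# ---------------------------------------------------------------------------

def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sampling_date", "death_date", "censor_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def write_phenotypes_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "code": str})
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_events_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    config: Mapping,
    inputs: Sequence = (),
    seed: Optional[int] = None,
) -> Path:
    """Record everything needed to reproduce a run byte-identically."""
    import chkit

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "seed": seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "versions": {
            "chkit": chkit.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
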