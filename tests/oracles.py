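"""Independent brute-force re-implementations used to cross-check the
filtering cascades. Each rule is a standalone predicate applied in
isolation; the oracle pass set is the intersection of all per-rule passes,
followed (for the WES cascade) by an O(n^2) transitive-closure cluster
collapse. Deliberately naive and kept free of chkit filtering internals.
"""

from collections import defaultdict


def _codon(protein_change):
    digits = "".join(c for c in protein_change if c.isdigit())
    return int(digits) if digits else None


def _exempt(v, exemptions):
    if v.protein_change is None:
        return False
    for gene, change in exemptions:
        if gene != v.gene:
            continue
        if change == v.protein_change:
            return True
        if change.isdigit() and _codon(v.protein_change) == int(change):
            return True
    return False


def wes_rule_predicates(panel):
    return {
        "R1": lambda v, ctx: v.gene in panel.genes,
        "R2": lambda v, ctx: v.gnomad_max_pop_af <= 0.001
        or _exempt(v, panel.hotspot_exemptions),
        "R3": lambda v, ctx: v.caller_label == "PASS",
        "R4": lambda v, ctx: v.somatic_quality >= 3,
        "R5": lambda v, ctx: v.germline_quality < 10,
        "R6": lambda v, ctx: v.total_depth >= 10 and v.alt_depth >= 2,
        "R7": lambda v, ctx: min(v.ref_fwd, v.ref_rev) >= 1 and min(v.alt_fwd, v.alt_rev) >= 1,
        "R8": lambda v, ctx: v.consequence != "splice"
        or (v.splice_distance_bp is not None and v.splice_distance_bp <= 2),
        "R9": lambda v, ctx: v.consequence != "frameshift"
        or ctx["fs_freq"].get((v.chrom, v.pos, v.ref, v.alt), 0.0) <= 0.0005,
    }


def lymphoid_rule_predicates(panel):
    rules = wes_rule_predicates(panel)
    rules["L1"] = lambda v, ctx: 0.02 <= v.alt_depth / v.total_depth <= 0.35
    rules["L2"] = lambda v, ctx: v.consequence != "missense" or (
        v.cosmic_count >= 3 or v.reported_lchip or v.reported_all
    )
    return rules


def panel_rule_predicates(panel):
    return {
        "P1": lambda v, ctx: v.caller_label == "PASS",
        "P2": lambda v, ctx: v.gnomad_max_pop_af <= 0.001,
        "P3": lambda v, ctx: ctx["af"].get((v.chrom, v.pos, v.ref, v.alt), 0.0) <= 0.01,
        "P4": lambda v, ctx: v.total_depth >= 100,
        "P5": lambda v, ctx: v.alt_depth >= 2,
        "P6": lambda v, ctx: v.alt_depth / v.total_depth <= 0.40,
        "P7": lambda v, ctx: min(v.ref_fwd, v.ref_rev) >= 1 and min(v.alt_fwd, v.alt_rev) >= 1,
        "P8": lambda v, ctx: v.alt_depth / v.total_depth >= 0.02,
    }


def cohort_fs_freq(table, n_samples):
    by_allele = defaultdict(set)
    for v in table:
        if v.consequence == "frameshift":
            by_allele[(v.chrom, v.pos, v.ref, v.alt)].add(v.sample_id)
    return {k: len(s) / n_samples for k, s in by_allele.items()}


def cohort_af(table, n_samples):
    by_allele = defaultdict(set)
    for v in table:
        by_allele[(v.chrom, v.pos, v.ref, v.alt)].add(v.sample_id)
    return {k: len(s) / n_samples for k, s in by_allele.items()}


def oracle_failed_rules(v, rules, ctx):
    return {rid for rid, pred in rules.items() if not pred(v, ctx)}


def oracle_pass_set(table, rules, ctx):
    """Intersection of per-rule passes, as variant identities (indices)."""
    return {
        i for i, v in enumerate(table) if not oracle_failed_rules(v, rules, ctx)
    }


def oracle_collapse(variants, window=5):
    """O(n^2) transitive-closure frameshift collapse for one sample.

    Returns the surviving subset (as a set of indices into ``variants``).
    """
    fs = [i for i, v in enumerate(variants) if v.consequence == "frameshift"]
    parent = {i: i for i in fs}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in fs:
        for b in fs:
            if a < b and variants[a].chrom == variants[b].chrom and abs(
                variants[a].pos - variants[b].pos
            ) <= window:
                parent[find(a)] = find(b)
    groups = defaultdict(list)
    for i in fs:
        groups[find(i)].append(i)
    keep = {i for i, v in enumerate(variants) if v.consequence != "frameshift"}
    for members in groups.values():
        def vaf(i):
            return variants[i].alt_depth / variants[i].total_depth
        best = sorted(members, key=lambda i: (-vaf(i), variants[i].pos, variants[i].alt))[0]
        keep.add(best)
    return keep


def oracle_wes_pass(table, panel, n_samples):
    """Full WES oracle: rule intersection then per-sample collapse.

    Returns the set of (sample_id, chrom, pos, ref, alt) keys that survive.
    """
    ctx = {"fs_freq": cohort_fs_freq(table, n_samples)}
    rules = wes_rule_predicates(panel)
    passing = [table[i] for i in sorted(oracle_pass_set(table, rules, ctx))]
    by_sample = defaultdict(list)
    for v in passing:
        by_sample[v.sample_id].append(v)
    out = set()
    for sample, vs in by_sample.items():
        for i in oracle_collapse(vs):
            v = vs[i]
            out.add((v.sample_id, v.chrom, v.pos, v.ref, v.alt))
    return out
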