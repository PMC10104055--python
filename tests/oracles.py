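"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results from first principles (exhaustive
enumeration, direct formulas) without calling the implementation paths they
check.
"""

import numpy as np


def brute_force_select(gene, contacts, linear_scope_bp=20000, min_count=0.5):
    """Enumerate every pixel and apply the three distal-contact filters directly.

    Filters: one anchor is the bin containing the TSS; the partner bin's
    interval lies entirely outside [TSS − scope, TSS + scope); count ≥
    min_count. Returns sorted (start, end, count) tuples.
    """
    res = contacts.resolution
    tss_bin = gene.tss // res
    out = []
    for i, j, c in contacts.pixels(gene.chrom):
        for a, b in ((i, j), (j, i)):
            if a != tss_bin or b == tss_bin:
                continue
            start, end = contacts.bin_interval(gene.chrom, b)
            overlaps = start < gene.tss + linear_scope_bp and end > gene.tss - linear_scope_bp
            if not overlaps and c >= min_count:
                out.append((start, end, c))
            break  # a pixel contributes at most once even if i == j
    return sorted(set(out))


def brute_force_classify(best_residuals, baseline_residuals, half_width):
    """Reclassify genes one at a time by direct interval membership."""
    both = spex_only = baseline_only = 0
    for rb, rs in zip(baseline_residuals, best_residuals):
        in_s = -half_width <= rs <= half_width
        in_b = -half_width <= rb <= half_width
        if in_s and in_b:
            both += 1
        elif in_s:
            spex_only += 1
        elif in_b:
            baseline_only += 1
    return both, spex_only, baseline_only


def random_contact_matrix(rng, resolution=1000, chrom="chrT", n_bins=60, n_pixels=40):
    """A random small symmetric matrix for oracle-equivalence checks."""
    from spex import ContactMatrix

    cm = ContactMatrix(resolution, {chrom: n_bins * resolution})
    for _ in range(n_pixels):
        i, j = sorted(rng.integers(0, n_bins, size=2))
        cm.add_pixel(chrom, int(i), int(j), float(rng.uniform(0, 2)))
    return cm
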